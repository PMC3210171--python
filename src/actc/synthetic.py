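"""Synthetic cartridge images and survival cohorts with known ground truth.

Every downstream stage of the pipeline is tested against this module: it
plants objects of four regimes (CTC-like, leukocyte, tumour micro particle,
auto-fluorescent debris) into four-channel tiles with a cartridge border in
the FITC channel, records each object's analytically computed true features,
and simulates patient cohorts whose survival depends on the true object
count through a proportional-hazards model.

Objects are rendered as disks with a Gaussian radial falloff
``I(d) = peak * exp(-d^2 / (2 * falloff^2))`` truncated at ``radius_px``.
CTC-regime objects use a steep falloff, which gives them the high CK-PE
standard deviation of a textured cytokeratin stain; leukocytes and debris
are nearly flat.  Background is truncated Gaussian (bounded support, so a
threshold above the background ceiling segments cleanly) and object signal
carries Poisson photon noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import CHANNELS, DEFAULT_PIXEL_AREA_UM2, ChannelStack

LABELS = ("ctc", "leukocyte", "tmp", "debris")


class ManifestError(ValueError):
    """Raised for manifests that cannot be rendered (overlap, out of range)."""


@dataclass(frozen=True)
class PlantedObject:
    """One ground-truth object: a disk at integer pixel ``(y, x)`` on a tile.

    ``ck_falloff`` is the Gaussian sigma (pixels) of the radial CK-PE
    profile; peaks are intensity counts within the configured bit depth.
    """

    tile: int
    y: int
    x: int
    radius_px: float
    ck_peak: float
    ck_falloff: float
    dapi_peak: float
    cd45_peak: float
    fitc_peak: float
    label: str

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


@dataclass
class SimConfig:
    """Study conditions for one simulated cartridge sample.

    Defaults emulate a full cartridge scan (144 tiles) at 8 bits with the
    0.448 µm²/pixel geometry; per-channel backgrounds are truncated Gaussians
    and the FITC channel carries a half-intensity cartridge border band of
    ``border_width_px`` along ``border_edges``.  ``object_counts`` are
    per-sample Poisson means per label.
    """

    n_tiles: int = 144
    tile_shape: tuple[int, int] = (256, 256)
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2
    bit_depth: int = 8
    background_mean: dict[str, float] = field(
        default_factory=lambda: {"fitc": 30.0, "ck": 10.0, "dapi": 12.0, "cd45": 10.0}
    )
    background_sd: dict[str, float] = field(
        default_factory=lambda: {"fitc": 1.5, "ck": 1.5, "dapi": 1.5, "cd45": 1.5}
    )
    background_clip_sigmas: float = 3.5
    border_width_px: int = 20
    border_edges: tuple[str, ...] = ("top", "bottom", "left", "right")
    border_intensity_factor: float = 0.5
    object_counts: dict[str, float] = field(
        default_factory=lambda: {"ctc": 8.0, "leukocyte": 30.0, "tmp": 15.0, "debris": 12.0}
    )
    min_separation_px: float = 2.0  # rim-to-rim overlap tolerance
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


#: per-label parameter regimes (uniform ranges; ``falloff_frac`` scales the
#: Gaussian sigma by the radius).  Chosen to straddle the classifier bounds:
#: CTC-regime objects land inside the optimal box, leukocytes fail on CD45
#: (and CK texture), micro particles fall under the 4 µm diameter with CK
#: texture above 10 counts, debris is CK-flat, DAPI-dim and FITC-bright.
LABEL_REGIMES: dict[str, dict] = {
    "ctc": dict(radius=(6.0, 8.5), ck_peak=(225.0, 255.0), falloff_frac=0.4,
                dapi_peak=(230.0, 255.0), cd45_peak=(2.0, 15.0), fitc_peak=(0.0, 8.0)),
    "leukocyte": dict(radius=(4.0, 6.0), ck_peak=(70.0, 110.0), falloff_frac=2.5,
                      dapi_peak=(200.0, 250.0), cd45_peak=(140.0, 220.0),
                      fitc_peak=(0.0, 8.0)),
    "tmp": dict(radius=(1.6, 2.4), ck_peak=(130.0, 180.0), falloff_frac=0.5,
                dapi_peak=(40.0, 90.0), cd45_peak=(2.0, 15.0), fitc_peak=(0.0, 8.0)),
    "debris": dict(radius=(3.5, 9.0), ck_peak=(60.0, 100.0), falloff_frac=3.0,
                   dapi_peak=(5.0, 40.0), cd45_peak=(5.0, 40.0),
                   fitc_peak=(90.0, 180.0)),
}


def make_object(
    label: str,
    tile: int,
    y: int,
    x: int,
    rng: np.random.Generator,
    radius: float | None = None,
) -> PlantedObject:
    """Draw one object of the given label regime at a fixed position."""
    reg = LABEL_REGIMES[label]
    if radius is None:
        radius = float(rng.uniform(*reg["radius"]))
    return PlantedObject(
        tile=tile, y=int(y), x=int(x),
        radius_px=radius,
        ck_peak=float(rng.uniform(*reg["ck_peak"])),
        ck_falloff=reg["falloff_frac"] * radius,
        dapi_peak=float(rng.uniform(*reg["dapi_peak"])),
        cd45_peak=float(rng.uniform(*reg["cd45_peak"])),
        fitc_peak=float(rng.uniform(*reg["fitc_peak"])),
        label=label,
    )


# ---------------------------------------------------------------------------
# analytic ground-truth features


def _disk_profile(obj: PlantedObject) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free CK profile on the rasterized disk support; returns
    (boolean support mask, CK intensity values over the mask)."""
    r = obj.radius_px
    n = int(math.ceil(r))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    d2 = (yy * yy + xx * xx).astype(float)
    mask = d2 <= r * r
    values = obj.ck_peak * np.exp(-d2[mask] / (2.0 * obj.ck_falloff**2))
    return mask, values


def true_features(obj: PlantedObject, pixel_area_um2: float) -> dict[str, float]:
    """Analytic feature vector of a planted object (no noise, full disk
    support): population CK std over the rasterized disk, channel peaks at
    the object center, and the disk pixel count."""
    mask, values = _disk_profile(obj)
    size_px = int(mask.sum())
    size_um2 = size_px * pixel_area_um2
    return {
        "ck_std": float(np.std(values)),
        "dapi_peak": obj.dapi_peak,
        "cd45_peak": obj.cd45_peak,
        "size_px": size_px,
        "size_um2": size_um2,
        "eq_diameter_um": 2.0 * math.sqrt(size_um2 / math.pi),
    }


# ---------------------------------------------------------------------------
# manifest generation


def _placement_margins(config: SimConfig, radius: float) -> tuple[int, int, int, int]:
    h, w = config.tile_shape
    b = config.border_width_px
    pad = int(math.ceil(radius)) + 2
    top = (b if "top" in config.border_edges else 0) + pad
    bottom = h - (b if "bottom" in config.border_edges else 0) - pad
    left = (b if "left" in config.border_edges else 0) + pad
    right = w - (b if "right" in config.border_edges else 0) - pad
    return top, bottom, left, right


def random_manifest(
    config: SimConfig,
    rng: np.random.Generator,
    counts: dict[str, int] | None = None,
) -> list[PlantedObject]:
    """Place objects uniformly inside the imaging area with non-overlapping
    disks.  ``counts`` fixes per-label totals; otherwise they are Poisson
    draws from ``config.object_counts``."""
    if counts is None:
        counts = {
            lab: int(rng.poisson(mean)) for lab, mean in config.object_counts.items()
        }
    placed: dict[int, list[tuple[int, int, float]]] = {}
    manifest: list[PlantedObject] = []
    for label in LABELS:
        for _ in range(int(counts.get(label, 0))):
            for _attempt in range(200):
                tile = int(rng.integers(config.n_tiles))
                reg = LABEL_REGIMES[label]
                radius = float(rng.uniform(*reg["radius"]))
                top, bottom, left, right = _placement_margins(config, radius)
                if bottom <= top or right <= left:
                    raise ManifestError("tile too small for object placement")
                y = int(rng.integers(top, bottom))
                x = int(rng.integers(left, right))
                ok = all(
                    math.hypot(y - py, x - px)
                    >= radius + pr + config.min_separation_px + 2.0
                    for py, px, pr in placed.get(tile, [])
                )
                if ok:
                    obj = make_object(label, tile, y, x, rng, radius=radius)
                    placed.setdefault(tile, []).append((y, x, radius))
                    manifest.append(obj)
                    break
            else:
                raise ManifestError(
                    f"could not place a {label} object without overlap"
                )
    return manifest


def _validate_manifest(config: SimConfig, manifest: list[PlantedObject]) -> None:
    maxval = config.max_count
    h, w = config.tile_shape
    by_tile: dict[int, list[PlantedObject]] = {}
    for i, obj in enumerate(manifest):
        for attr in ("ck_peak", "dapi_peak", "cd45_peak", "fitc_peak"):
            v = getattr(obj, attr)
            if not (0 <= v <= maxval):
                raise ManifestError(
                    f"object {i} ({obj.label}, tile {obj.tile}): {attr}={v} "
                    f"outside [0, {maxval}]"
                )
        if not (0 <= obj.tile < config.n_tiles):
            raise ManifestError(f"object {i}: tile {obj.tile} out of range")
        r = obj.radius_px
        if not (r <= obj.y <= h - 1 - r and r <= obj.x <= w - 1 - r):
            raise ManifestError(
                f"object {i} ({obj.label}) does not fit within tile bounds"
            )
        by_tile.setdefault(obj.tile, []).append(obj)
    for tile, objs in by_tile.items():
        for a in range(len(objs)):
            for b in range(a + 1, len(objs)):
                oa, ob = objs[a], objs[b]
                dist = math.hypot(oa.y - ob.y, oa.x - ob.x)
                if dist < oa.radius_px + ob.radius_px + config.min_separation_px:
                    raise ManifestError(
                        f"objects overlap beyond tolerance on tile {tile}: "
                        f"{oa.label} at ({oa.y},{oa.x}) and {ob.label} at "
                        f"({ob.y},{ob.x})"
                    )


# ---------------------------------------------------------------------------
# rendering


def _render_signal(
    signal: np.ndarray, obj: PlantedObject, peak: float, sigma: float
) -> None:
    r = obj.radius_px
    n = int(math.ceil(r))
    h, w = signal.shape
    y0, y1 = max(obj.y - n, 0), min(obj.y + n + 1, h)
    x0, x1 = max(obj.x - n, 0), min(obj.x + n + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = ((yy - obj.y) ** 2 + (xx - obj.x) ** 2).astype(float)
    support = d2 <= r * r
    patch = np.zeros_like(d2)
    patch[support] = peak * np.exp(-d2[support] / (2.0 * sigma**2))
    signal[y0:y1, x0:x1] += patch


def simulate_cartridge(
    config: SimConfig,
    manifest: list[PlantedObject],
    rng: np.random.Generator | None = None,
) -> tuple[ChannelStack, pd.DataFrame]:
    """Render a sample stack from a manifest; returns the stack and the
    ground-truth table (one row per object with its true features).

    Background is a truncated Gaussian per channel (clipped at
    ``background_clip_sigmas``), object signal carries Poisson noise, and the
    FITC channel is darkened to ``border_intensity_factor`` of background in
    the cartridge-border band.  Deterministic for a fixed ``config.rng_seed``
    (or caller-supplied generator).
    """
    _validate_manifest(config, manifest)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    h, w = config.tile_shape
    maxval = config.max_count
    dtype = np.uint8 if config.bit_depth <= 8 else np.uint16

    # noiseless per-channel signal, rendered per tile
    signal = np.zeros((config.n_tiles, 4, h, w), dtype=float)
    chan_idx = {name: i for i, name in enumerate(CHANNELS)}
    for obj in manifest:
        wide = 0.8 * obj.radius_px
        _render_signal(signal[obj.tile, chan_idx["ck"]], obj, obj.ck_peak, obj.ck_falloff)
        _render_signal(signal[obj.tile, chan_idx["dapi"]], obj, obj.dapi_peak, wide)
        _render_signal(signal[obj.tile, chan_idx["cd45"]], obj, obj.cd45_peak, wide)
        if obj.fitc_peak > 0:
            _render_signal(signal[obj.tile, chan_idx["fitc"]], obj, obj.fitc_peak, wide)

    tiles = np.empty((config.n_tiles, 4, h, w), dtype=dtype)
    clip = config.background_clip_sigmas
    for name, c in chan_idx.items():
        mean = config.background_mean[name]
        sd = config.background_sd[name]
        bg = mean + sd * np.clip(
            rng.standard_normal((config.n_tiles, h, w)), -clip, clip
        )
        if name == "fitc":
            bg *= _border_field(config)
        noisy = bg + rng.poisson(signal[:, c]).astype(float)
        tiles[:, c] = np.clip(np.rint(noisy), 0, maxval).astype(dtype)

    stack = ChannelStack(
        tiles=tiles,
        channel_roles=dict(chan_idx),
        bit_depth=config.bit_depth,
        pixel_area_um2=config.pixel_area_um2,
    )
    return stack, manifest_table(config, manifest)


def _border_field(config: SimConfig) -> np.ndarray:
    """Multiplicative FITC border mask: ``border_intensity_factor`` in the
    border band, 1 inside the imaging area.  Shape (1, H, W) for broadcast."""
    h, w = config.tile_shape
    f = np.ones((h, w))
    b, fac = config.border_width_px, config.border_intensity_factor
    if b > 0:
        if "top" in config.border_edges:
            f[:b, :] = fac
        if "bottom" in config.border_edges:
            f[h - b :, :] = fac
        if "left" in config.border_edges:
            f[:, :b] = fac
        if "right" in config.border_edges:
            f[:, w - b :] = fac
    return f[None, :, :]


def manifest_table(config: SimConfig, manifest: list[PlantedObject]) -> pd.DataFrame:
    """Ground-truth table: id, position, label and analytic true features."""
    rows = []
    for i, obj in enumerate(manifest):
        rows.append(
            {
                "object_id": i, "tile": obj.tile, "y": obj.y, "x": obj.x,
                "label": obj.label, "radius_px": obj.radius_px,
                **true_features(obj, config.pixel_area_um2),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["object_id", "tile", "y", "x", "label", "radius_px", "ck_std",
                 "dapi_peak", "cd45_peak", "size_px", "size_um2", "eq_diameter_um"],
    )


def simulate_sample(
    config: SimConfig, counts: dict[str, int] | None = None
) -> tuple[ChannelStack, pd.DataFrame]:
    """Convenience: random manifest + rendering from ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    manifest = random_manifest(config, rng, counts=counts)
    return simulate_cartridge(config, manifest, rng=rng)


def simulate_controls(
    config: SimConfig, n_samples: int
) -> list[tuple[ChannelStack, pd.DataFrame]]:
    """Healthy-control samples: leukocytes, debris and micro-particle-scale
    objects, but no object in the CTC feature regime."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    out = []
    for k in range(n_samples):
        cfg = replace(
            config,
            rng_seed=config.rng_seed + k,
            object_counts={
                lab: mean for lab, mean in config.object_counts.items() if lab != "ctc"
            },
        )
        out.append(simulate_sample(cfg))
    return out


# ---------------------------------------------------------------------------
# survival cohorts


@dataclass
class SurvivalSimConfig:
    """Cohort with exponential survival tied to a per-patient object count.

    Patients with ``count >= cutoff_link`` have their hazard multiplied by
    ``true_hr``.  Counts follow a negative binomial (heavy-tailed, like CTC
    counts); censoring is independent exponential.  ``baseline_hazard`` and
    ``censoring_rate`` are per month; the defaults give a median survival of
    roughly 20 months in the low-count group and mild censoring.
    """

    n_patients: int = 185
    true_hr: float = 3.0
    baseline_hazard: float = 0.025
    censoring_rate: float = 0.008
    count_mean: float = 8.0
    count_dispersion: float = 0.6  # negative-binomial shape; smaller = heavier tail
    cutoff_link: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be nonnegative")


def simulate_cohort(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate a patient cohort table (id, count, os_months, event)."""
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients
    shape = config.count_dispersion
    p = shape / (shape + config.count_mean)
    counts = rng.negative_binomial(shape, p, size=n)
    high = counts >= config.cutoff_link
    hazard = config.baseline_hazard * np.where(high, config.true_hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [f"p{i:04d}" for i in range(n)],
            "timepoint": "baseline",
            "count_auto": counts.astype(int),
            "os_months": np.maximum(time, 1e-6),
            "event": event,
        }
    )


# ---------------------------------------------------------------------------
# feature-space cohorts for classifier training


@dataclass
class FeatureCohortConfig:
    """Feature-space study for the classifier search: per-patient object
    tables where only objects inside a planted feature box carry prognostic
    signal.

    Signal objects sit inside ``box``; two risk-independent nuisance
    populations mimic sub-threshold debris (CK texture below the box) and
    leukocytes (CD45 above the box).  Follow-up samples separate risk groups
    more sharply than baseline, and controls contain nuisance objects only.
    """

    n_patients: int = 200
    n_controls: int = 20
    true_hr: float = 3.0
    baseline_hazard: float = 0.03
    censoring_rate: float = 0.005
    box: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ck_std": (50.0, 85.0), "cd45_peak": (0.0, 60.0)}
    )
    debris_ck_range: tuple[float, float] = (20.0, 50.0)
    leuko_cd45_range: tuple[float, float] = (60.0, 140.0)
    signal_mean: tuple[float, float] = (1.5, 9.0)  # (low-risk, high-risk) baseline
    followup_signal_mean: tuple[float, float] = (0.5, 7.0)
    nuisance_mean: float = 8.0
    rng_seed: int = 0


def _nuisance_objects(cfg: FeatureCohortConfig, rng, n_debris: int, n_leuko: int):
    ck_lo, ck_hi = cfg.box["ck_std"]
    rows = []
    for _ in range(n_debris):
        rows.append(
            dict(ck_std=rng.uniform(*cfg.debris_ck_range),
                 cd45_peak=rng.uniform(*cfg.box["cd45_peak"])))
    for _ in range(n_leuko):
        rows.append(
            dict(ck_std=rng.uniform(ck_lo, ck_hi),
                 cd45_peak=rng.uniform(*cfg.leuko_cd45_range)))
    return rows


def _fill_extras(rows: list[dict], rng) -> None:
    for r in rows:
        r["dapi_peak"] = rng.uniform(0.0, 255.0)   # non-informative
        r["size_px"] = rng.uniform(20.0, 600.0)    # non-informative


def simulate_feature_cohort(cfg: FeatureCohortConfig) -> dict:
    """Simulate baseline/follow-up feature tables + cohort, and controls.

    Returns a dict with keys ``baseline`` and ``followup`` (each a
    ``(features, cohort)`` pair), ``controls`` (feature table),
    ``n_control_samples`` and ``true_box``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_patients
    risk = rng.integers(0, 2, size=n)  # latent high-risk flag

    hazard = cfg.baseline_hazard * np.where(risk == 1, cfg.true_hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = (
        rng.exponential(1.0 / cfg.censoring_rate, size=n)
        if cfg.censoring_rate > 0
        else np.full(n, np.inf)
    )
    time = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    event = (t_event <= t_cens).astype(int)
    ids = [f"p{i:04d}" for i in range(n)]

    def build_tables(signal_means: tuple[float, float]) -> pd.DataFrame:
        lo_mean, hi_mean = signal_means
        rows = []
        for i in range(n):
            n_sig = rng.poisson(hi_mean if risk[i] else lo_mean)
            n_deb = rng.poisson(cfg.nuisance_mean)
            n_leu = rng.poisson(cfg.nuisance_mean)
            objs = [
                dict(ck_std=rng.uniform(*cfg.box["ck_std"]),
                     cd45_peak=rng.uniform(*cfg.box["cd45_peak"]))
                for _ in range(n_sig)
            ]
            objs += _nuisance_objects(cfg, rng, n_deb, n_leu)
            _fill_extras(objs, rng)
            for o in objs:
                o["sample_id"] = ids[i]
            rows.extend(objs)
        return pd.DataFrame(
            rows, columns=["sample_id", "ck_std", "cd45_peak", "dapi_peak", "size_px"]
        )

    cohort = pd.DataFrame(
        {"sample_id": ids, "os_months": time, "event": event, "risk": risk}
    )
    baseline_feats = build_tables(cfg.signal_mean)
    followup_feats = build_tables(cfg.followup_signal_mean)

    ctl_rows = []
    for k in range(cfg.n_controls):
        objs = _nuisance_objects(
            cfg, rng, rng.poisson(cfg.nuisance_mean), rng.poisson(cfg.nuisance_mean)
        )
        _fill_extras(objs, rng)
        for o in objs:
            o["sample_id"] = f"c{k:03d}"
        ctl_rows.extend(objs)
    controls = pd.DataFrame(
        ctl_rows, columns=["sample_id", "ck_std", "cd45_peak", "dapi_peak", "size_px"]
    )

    return {
        "baseline": (baseline_feats, cohort),
        "followup": (followup_feats, cohort),
        "controls": controls,
        "n_control_samples": cfg.n_controls,
        "true_box": dict(cfg.box),
    }
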