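"""Synthetic TCSPC FLIM acquisitions of exfoliated-cell phantoms.

The generator reproduces the statistical structure the analysis assumes:
each clinical group (cervical cancer, high-grade CIN, benign, normal) is
characterised by the distribution of the amplitude-weighted mean NAD(P)H
lifetime ``tm`` and the protein-bound fraction ``a2`` observed on real
cells; per-cell decay parameters are drawn from those distributions, cells
are placed as elliptical phantoms, and photon counts follow a biexponential
decay with Poisson shot noise on top of a uniform background.

Cancer cells favour glycolysis (the Warburg effect), which shortens tm and
lowers a2 — the group means encode exactly that gradient.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import AcquisitionConfig, TCSPCImage

__all__ = [
    "GroupProfile",
    "DEFAULT_GROUP_PROFILES",
    "CellPhantom",
    "CohortSpec",
    "ImageRecord",
    "PatientRecord",
    "CohortBundle",
    "LayoutError",
    "sample_cell_params",
    "render_cell_layout",
    "decay_profile",
    "expected_counts",
    "simulate_tcspc_image",
    "inject_artifacts",
    "generate_cohort",
    "iter_patients",
]

# Truncation bounds keeping the tm -> t2 inversion stable (documented
# constants, not measured values).
A2_FLOOR = 0.05
TM_MARGIN_PS = 1.0

MALIGNANT_GROUPS = ("CC", "CINII/III")


class LayoutError(RuntimeError):
    """Raised when cell phantoms cannot be placed under the constraints."""


@dataclass(frozen=True)
class GroupProfile:
    """Group-level distribution of (tm, a2) image-peak statistics.

    ``tm`` in picoseconds, ``a2`` in percent; means/SDs describe the
    per-cell variation within the group.
    """

    group: str
    tm_mean_ps: float
    tm_sd_ps: float
    a2_mean_pct: float
    a2_sd_pct: float

    def __post_init__(self) -> None:
        if self.tm_mean_ps <= 0:
            raise ValueError("tm_mean_ps must be positive")
        if not 0 <= self.a2_mean_pct <= 100:
            raise ValueError("a2_mean_pct must lie in [0, 100]")
        if self.tm_sd_ps < 0 or self.a2_sd_pct < 0:
            raise ValueError("standard deviations must be >= 0")


#: Group lifetime statistics: mean +/- SD of tm (ps) and a2 (%) per group.
DEFAULT_GROUP_PROFILES: dict[str, GroupProfile] = {
    "CC": GroupProfile("CC", 647.0, 137.0, 21.7, 28.1),
    "CINII/III": GroupProfile("CINII/III", 805.0, 187.0, 57.8, 31.4),
    "benign": GroupProfile("benign", 878.0, 91.0, 90.6, 13.8),
    "normal": GroupProfile("normal", 928.0, 70.0, 93.4, 8.2),
}


@dataclass
class CellPhantom:
    """Elliptical cell phantom with one biexponential decay parameter pair."""

    center: tuple[float, float]      # (row, col) in pixels
    axes: tuple[float, float]        # semi-axes in pixels
    orientation: float               # radians
    nucleus_fraction: float          # nucleus radius / cell radius
    a2_frac: float
    t2_ps: float
    amplitude: float                 # expected signal photons per pixel

    def __post_init__(self) -> None:
        if not 0.0 <= self.a2_frac <= 1.0:
            raise ValueError("a2_frac must lie in [0, 1]")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: how many patients per group and images per patient.

    ``malignant_image_fraction`` gives, per group, the probability that an
    image is drawn from that group's (malignant) profile rather than the
    normal-like baseline — cancer samples contain a mixture of malignant
    and normal-looking cells, so not every image from a cancer patient is
    abnormal.
    """

    patients_per_group: dict = field(
        default_factory=lambda: {"normal": 14, "CC": 5, "CINII/III": 4})
    images_per_patient: int = 10
    cells_per_image: tuple[int, int] = (2, 8)
    malignant_image_fraction: dict = field(
        default_factory=lambda: {"CC": 1.0, "CINII/III": 0.75,
                                 "benign": 0.0, "normal": 0.0})
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.patients_per_group.items():
            if n < 1:
                raise ValueError(f"patient count for {g!r} must be >= 1")
        if self.images_per_patient < 1:
            raise ValueError("images_per_patient must be >= 1")
        lo, hi = self.cells_per_image
        if lo < 0 or hi < lo:
            raise ValueError("cells_per_image must be a (lo, hi) range")
        for g, f in self.malignant_image_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"malignant_image_fraction[{g!r}] not in [0,1]")


@dataclass
class ImageRecord:
    """One simulated acquisition with its ground truth."""

    image_id: str
    image: TCSPCImage
    truth_label: str                 # "normal" or "abnormal"
    origin_group: str                # profile the cell parameters came from
    phantoms: list
    param_maps: dict                 # a2, t2, tm, amplitude, cell_label


@dataclass
class PatientRecord:
    patient_id: str
    group: str
    images: list


@dataclass
class CohortBundle:
    spec: CohortSpec
    config: AcquisitionConfig
    patients: list

    @property
    def n_images(self) -> int:
        return sum(len(p.images) for p in self.patients)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_cell_params(profile: GroupProfile, config: AcquisitionConfig,
                       rng_seed) -> tuple[float, float]:
    """Draw one cell's (a2, t2) consistent with the group's tm/a2 statistics.

    tm is drawn from a truncated normal on (t1 + 1 ps, period/2) and a2
    from a truncated normal on [0.05, 1]; the slow lifetime follows from
    inverting tm = (1 - a2) t1 + a2 t2, clamped to [t1, period/2].
    """
    if not isinstance(profile, GroupProfile):
        raise TypeError("profile must be a GroupProfile")
    rng = _as_rng(rng_seed)
    t1 = config.t1_ps
    half_period = config.period_ps / 2.0

    tm = _trunc_normal(profile.tm_mean_ps, profile.tm_sd_ps,
                       t1 + TM_MARGIN_PS, half_period, rng)
    a2 = _trunc_normal(profile.a2_mean_pct / 100.0, profile.a2_sd_pct / 100.0,
                       A2_FLOOR, 1.0, rng)
    t2 = (tm - (1.0 - a2) * t1) / a2
    t2 = float(np.clip(t2, t1, half_period))
    return float(a2), t2


def _trunc_normal(mean: float, sd: float, lo: float, hi: float,
                  rng: np.random.Generator) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def render_cell_layout(n_cells: int, profile: GroupProfile,
                       config: AcquisitionConfig, seed, *,
                       amplitude_mean: float = 500.0,
                       nucleus_fraction: float = 0.35,
                       nucleus_amp_factor: float = 0.7,
                       allow_overlap: bool = False,
                       max_tries: int = 200):
    """Place elliptical cell phantoms and rasterise their parameter maps.

    Returns ``(phantoms, param_maps)`` where ``param_maps`` holds per-pixel
    ``a2``, ``t2``, ``tm``, ``amplitude`` and an integer ``cell_label``
    (0 = background). Deterministic given the seed.
    """
    rng = _as_rng(seed)
    n = config.image_size_px
    phantoms: list[CellPhantom] = []
    for _ in range(n_cells):
        placed = False
        for _attempt in range(max_tries):
            major = rng.uniform(0.055, 0.095) * n
            minor = major * rng.uniform(0.6, 1.0)
            margin = major + 1
            cy = rng.uniform(margin, n - margin)
            cx = rng.uniform(margin, n - margin)
            if not allow_overlap:
                clash = any(
                    math.hypot(cy - p.center[0], cx - p.center[1])
                    < 0.9 * (major + max(p.axes))
                    for p in phantoms)
                if clash:
                    continue
            a2, t2 = sample_cell_params(profile, config, rng)
            amp = amplitude_mean * rng.uniform(0.7, 1.3)
            phantoms.append(CellPhantom(
                center=(cy, cx), axes=(major, minor),
                orientation=rng.uniform(0, math.pi),
                nucleus_fraction=nucleus_fraction,
                a2_frac=a2, t2_ps=t2, amplitude=amp))
            placed = True
            break
        if not placed:
            raise LayoutError(
                f"could not place cell {len(phantoms) + 1}/{n_cells} without "
                f"overlap after {max_tries} tries (image {n}x{n} px)")

    a2_map = np.zeros((n, n), dtype=np.float64)
    t2_map = np.zeros((n, n), dtype=np.float64)
    amp_map = np.zeros((n, n), dtype=np.float64)
    label = np.zeros((n, n), dtype=np.int32)
    yy, xx = np.mgrid[0:n, 0:n]
    for i, p in enumerate(phantoms, start=1):
        dy, dx = yy - p.center[0], xx - p.center[1]
        c, s = math.cos(p.orientation), math.sin(p.orientation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        r2 = (u / p.axes[0]) ** 2 + (v / p.axes[1]) ** 2
        inside = r2 <= 1.0
        nucleus = r2 <= p.nucleus_fraction ** 2
        label[inside] = i
        a2_map[inside] = p.a2_frac
        t2_map[inside] = p.t2_ps
        amp_map[inside] = p.amplitude
        amp_map[nucleus] = p.amplitude * nucleus_amp_factor
    tm_map = np.where(label > 0,
                      (1.0 - a2_map) * config.t1_ps + a2_map * t2_map, 0.0)
    param_maps = {"a2": a2_map, "t2": t2_map, "tm": tm_map,
                  "amplitude": amp_map, "cell_label": label}
    return phantoms, param_maps


def decay_profile(a2: np.ndarray, t2: np.ndarray,
                  config: AcquisitionConfig) -> np.ndarray:
    """Normalised biexponential bin profile(s): rows sum to 1.

    Each exponential is normalised over the period so that multiplying by
    an amplitude yields that expected number of signal photons in total.
    """
    tau = config.bin_centers_ps
    a2 = np.atleast_1d(np.asarray(a2, dtype=np.float64))
    t2 = np.atleast_1d(np.asarray(t2, dtype=np.float64))
    e1 = np.exp(-tau / config.t1_ps)
    e1 /= e1.sum()
    e2 = np.exp(-tau[None, :] / t2[:, None])
    e2 /= e2.sum(axis=1, keepdims=True)
    return (1.0 - a2)[:, None] * e1[None, :] + a2[:, None] * e2


def expected_counts(param_maps: dict, config: AcquisitionConfig) -> np.ndarray:
    """Expected per-bin counts for every pixel (float array y, x, t)."""
    a2 = np.asarray(param_maps["a2"], dtype=np.float64)
    t2 = np.asarray(param_maps["t2"], dtype=np.float64)
    amp = np.asarray(param_maps["amplitude"], dtype=np.float64)
    if not (np.isfinite(a2).all() and np.isfinite(t2).all()
            and np.isfinite(amp).all()):
        raise ValueError("parameter maps must be finite")
    if (amp < 0).any():
        raise ValueError("amplitudes must be >= 0")

    # Pixels share per-cell parameters, so collapse to unique (a2, t2) pairs.
    pairs = np.stack([a2.ravel(), np.where(t2.ravel() > 0, t2.ravel(),
                                           config.t1_ps)], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    profiles = decay_profile(uniq[:, 0], uniq[:, 1], config)
    shape = a2.shape + (config.n_time_bins,)
    expected = (amp.ravel()[:, None] * profiles[inverse]).reshape(shape)
    return expected + config.background_rate


def simulate_tcspc_image(param_maps: dict, config: AcquisitionConfig,
                         seed) -> TCSPCImage:
    """Poisson-sample a TCSPC stack from per-pixel decay parameters.

    Signal photons are drawn per decaying pixel; background photons,
    independent and uniform over (pixel, bin), are drawn as one Poisson
    total and scattered — by superposition this equals drawing Poisson
    counts from the summed expectation at every pixel.
    """
    rng = _as_rng(seed)
    a2 = np.asarray(param_maps["a2"], dtype=np.float64)
    t2 = np.asarray(param_maps["t2"], dtype=np.float64)
    amp = np.asarray(param_maps["amplitude"], dtype=np.float64)
    if not (np.isfinite(a2).all() and np.isfinite(t2).all()
            and np.isfinite(amp).all()):
        raise ValueError("parameter maps must be finite")
    if (amp < 0).any():
        raise ValueError("amplitudes must be >= 0")
    ny, nx = amp.shape
    nt = config.n_time_bins
    counts = np.zeros((ny, nx, nt), dtype=np.int64)

    sig = amp > 0
    if sig.any():
        pairs = np.stack([a2[sig], np.where(t2[sig] > 0, t2[sig],
                                            config.t1_ps)], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        profiles = decay_profile(uniq[:, 0], uniq[:, 1], config)
        expected_sig = amp[sig][:, None] * profiles[inverse]
        counts[sig] = rng.poisson(expected_sig)

    if config.background_rate > 0:
        n_bg = rng.poisson(config.background_rate * ny * nx * nt)
        if n_bg:
            flat = rng.integers(0, ny * nx * nt, size=n_bg)
            counts_flat = counts.reshape(-1)
            np.add.at(counts_flat, flat, 1)

    meta = {"background_rate": config.background_rate, "t1_ps": config.t1_ps,
            "synthetic": True}
    return TCSPCImage(counts=counts.astype(np.uint16),
                      bin_width_ps=config.bin_width_ps, meta=meta)


def _cell_mask_from_counts(image: TCSPCImage) -> np.ndarray:
    intensity = image.intensity()
    bg = image.meta.get("background_rate", 0.0) * image.n_time_bins
    thr = max(bg + 5.0 * math.sqrt(bg + 1.0), 0.1 * intensity.max())
    return intensity > thr


def inject_artifacts(image: TCSPCImage, kind: str, severity: float,
                     seed) -> TCSPCImage:
    """Contaminate an acquisition the way unqualified clinical images are.

    ``bright_debris`` adds one high-amplitude short-lifetime blob in a
    non-cellular region (debris outshining the cells); ``neutrophil_clutter``
    scatters many small bright speckles over roughly ``severity`` of the
    cell area (neutrophils covering the exfoliated cells).
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if kind not in ("bright_debris", "neutrophil_clutter"):
        raise ValueError(f"unknown artifact kind {kind!r}")
    counts = image.counts.astype(np.int64, copy=True)
    if severity == 0.0:
        return TCSPCImage(counts=counts, bin_width_ps=image.bin_width_ps,
                          meta=dict(image.meta))
    rng = _as_rng(seed)
    ny, nx, nt = counts.shape
    tau = image.bin_centers_ps
    t1 = image.meta.get("t1_ps", 460.0)
    prof = np.exp(-tau / t1)
    prof /= prof.sum()
    cell = _cell_mask_from_counts(image)
    peak_cell = counts.sum(axis=2)[cell].max() if cell.any() else counts.sum()

    if kind == "bright_debris":
        from scipy.ndimage import binary_dilation
        radius = (0.05 + 0.15 * severity) * min(ny, nx)
        # debris lives in the non-cellular area, clear of the cell margin
        near_cell = binary_dilation(cell, iterations=2) if cell.any() else cell
        free = np.argwhere(~near_cell)
        if len(free) == 0:
            free = np.argwhere(np.ones_like(cell))
        cy, cx = free[rng.integers(len(free))]
        yy, xx = np.mgrid[0:ny, 0:nx]
        blob = ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2) & ~near_cell
        amp = (1.0 + 4.0 * severity) * max(peak_cell, 1)
        extra = rng.poisson(amp * prof[None, :],
                            size=(int(blob.sum()), nt))
        counts[blob] += extra
    else:  # neutrophil_clutter
        cell_idx = np.argwhere(cell)
        if len(cell_idx) == 0:
            raise ValueError("no cell area found to clutter")
        target = int(round(severity * len(cell_idx)))
        covered = np.zeros((ny, nx), dtype=bool)
        med_cell = max(np.median(counts.sum(axis=2)[cell]), 1)
        yy, xx = np.mgrid[0:ny, 0:nx]
        guard = 0
        while covered[cell].sum() < target and guard < 10 * len(cell_idx):
            guard += 1
            cy, cx = cell_idx[rng.integers(len(cell_idx))]
            r = rng.integers(1, 3)
            spot = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2) & cell
            new = spot & ~covered
            if not new.any():
                continue
            covered |= spot
            extra = rng.poisson(3.0 * med_cell * prof[None, :],
                                size=(int(new.sum()), nt))
            counts[new] += extra
    return TCSPCImage(counts=counts, bin_width_ps=image.bin_width_ps,
                      meta=dict(image.meta))


def _patient_seed_seqs(spec: CohortSpec):
    groups = list(spec.patients_per_group.items())
    total = sum(n for _, n in groups)
    root = np.random.SeedSequence(spec.seed)
    return root.spawn(total)


def iter_patients(spec: CohortSpec,
                  profiles: dict | None = None,
                  config: AcquisitionConfig | None = None):
    """Lazily yield PatientRecord objects (images materialised per patient).

    Deterministic given ``spec.seed``; `generate_cohort` materialises the
    same stream.
    """
    profiles = dict(DEFAULT_GROUP_PROFILES if profiles is None else profiles)
    config = AcquisitionConfig() if config is None else config
    normal_profile = profiles["normal"]
    seqs = _patient_seed_seqs(spec)
    idx = 0
    for group, n_pat in spec.patients_per_group.items():
        if group not in profiles:
            raise ValueError(f"no profile for group {group!r}")
        frac = spec.malignant_image_fraction.get(group, 0.0)
        for p in range(n_pat):
            pseq = seqs[idx]
            idx += 1
            rng = np.random.default_rng(pseq)
            patient_id = f"{group.replace('/', '')}-{p + 1:02d}"
            images = []
            for im in range(spec.images_per_patient):
                abnormal = bool(rng.random() < frac) and group in MALIGNANT_GROUPS
                if abnormal:
                    profile = profiles[group]
                elif group in ("benign", "normal"):
                    profile = profiles[group]
                else:
                    profile = normal_profile
                n_cells = int(rng.integers(spec.cells_per_image[0],
                                           spec.cells_per_image[1] + 1))
                phantoms, maps = render_cell_layout(
                    n_cells, profile, config, rng)
                image = simulate_tcspc_image(maps, config, rng)
                images.append(ImageRecord(
                    image_id=f"{patient_id}_img{im + 1:02d}",
                    image=image,
                    truth_label="abnormal" if abnormal else "normal",
                    origin_group=profile.group,
                    phantoms=phantoms,
                    param_maps=maps))
            yield PatientRecord(patient_id=patient_id, group=group,
                                images=images)


def generate_cohort(spec: CohortSpec,
                    profiles: dict | None = None,
                    config: AcquisitionConfig | None = None) -> CohortBundle:
    """Materialise a full synthetic cohort with ground truth attached."""
    config = AcquisitionConfig() if config is None else config
    patients = list(iter_patients(spec, profiles, config))
    return CohortBundle(spec=spec, config=config, patients=patients)
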