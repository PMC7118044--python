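"""Synthetic data generation for every stage of the pipeline.

Emulates the study design — two genotypes (WT, HET) imaged longitudinally at
6, 12 and 16 months, six brain regions quantified from 90-min dynamic scans —
so that kinetic modelling, image-space extraction, group statistics and
in-vitro densitometry can all be exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    DynamicImage,
    FrameSchedule,
    InputFunctionParams,
    KineticParams,
    LabelAtlas,
    TimeActivityCurve,
    fine_time_grid,
    frame_average,
    input_function,
    study_frame_schedule,
    tissue_curve_2tcm,
)

__all__ = [
    "DEFAULT_NOISE_SCALE",
    "LOW_NOISE_SCALE",
    "NOISE_FLOOR_KBQ",
    "CohortConfig",
    "SubjectScan",
    "CohortData",
    "PhantomSpec",
    "add_frame_noise",
    "rates_for_target_vt",
    "default_vt_table",
    "default_cohort_config",
    "generate_cohort",
    "default_phantom_spec",
    "generate_phantom_scan",
    "DEFAULT_STANDARDS",
    "generate_section_images",
]

#: default count-statistics noise scale for regional TACs
DEFAULT_NOISE_SCALE = 0.1
#: low-noise setting used for estimator-agreement studies
LOW_NOISE_SCALE = 0.05
#: activity floor (kBq/cm^3) entering the variance model
NOISE_FLOOR_KBQ = 0.1

GENOTYPES = ("WT", "HET")
AGES_MONTHS = (6, 12, 16)
REGIONS = ("cerebellum", "thalamus", "striatum", "motor_cortex", "hippocampus", "pons")

# Group-mean V_T (mL/cm^3) and between-subject SD per genotype x age x region.
# Cerebellum (all ages) and striatum at 6 months carry the literature values;
# the remaining cells are plausible defaults consistent with the regional
# rank order (cerebellum > thalamus > cortex > hippocampus > striatum > pons
# among quantified V_T), the HET elevation in non-striatal regions, and the
# genotype-independent ~17% decline from 6 to 12 months.
_VT_TABLE = {
    # region: {(genotype, age): (mean, sd)}
    "cerebellum": {
        ("WT", 6): (6.61, 0.74), ("HET", 6): (7.61, 1.32),
        ("WT", 12): (5.48, 0.93), ("HET", 12): (6.61, 0.74),
        ("WT", 16): (5.66, 0.72), ("HET", 16): (6.66, 0.65),
    },
    "striatum": {
        ("WT", 6): (4.49, 0.43), ("HET", 6): (4.69, 0.63),
        ("WT", 12): (3.72, 0.45), ("HET", 12): (3.88, 0.55),
        ("WT", 16): (3.75, 0.45), ("HET", 16): (3.90, 0.55),
    },
    "thalamus": {
        ("WT", 6): (5.20, 0.60), ("HET", 6): (5.90, 0.80),
        ("WT", 12): (4.30, 0.60), ("HET", 12): (4.90, 0.70),
        ("WT", 16): (4.40, 0.60), ("HET", 16): (4.90, 0.70),
    },
    "motor_cortex": {
        ("WT", 6): (4.80, 0.50), ("HET", 6): (5.30, 0.70),
        ("WT", 12): (4.00, 0.50), ("HET", 12): (4.30, 0.60),
        ("WT", 16): (4.10, 0.50), ("HET", 16): (4.60, 0.60),
    },
    "hippocampus": {
        ("WT", 6): (4.60, 0.50), ("HET", 6): (5.10, 0.70),
        ("WT", 12): (3.80, 0.50), ("HET", 12): (4.10, 0.60),
        ("WT", 16): (3.90, 0.50), ("HET", 16): (4.40, 0.60),
    },
    "pons": {
        ("WT", 6): (3.40, 0.40), ("HET", 6): (3.70, 0.50),
        ("WT", 12): (2.80, 0.40), ("HET", 12): (3.10, 0.45),
        ("WT", 16): (2.90, 0.40), ("HET", 16): (3.20, 0.45),
    },
}


def default_vt_table() -> pd.DataFrame:
    """Tidy table of true group-mean V_T and between-subject SD."""
    rows = [
        {"region": region, "genotype": g, "age_months": a, "mean_vt": m, "sd_vt": s}
        for region, cells in _VT_TABLE.items()
        for (g, a), (m, s) in cells.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def add_frame_noise(tac: TimeActivityCurve, noise_scale: float, seed) -> TimeActivityCurve:
    """Add count-statistics-like noise to a framed TAC.

    Per-frame SD = ``noise_scale * sqrt(max(activity, floor) / frame_minutes)``
    — variance inversely proportional to frame duration and proportional to
    activity, the standard approximation for decay-corrected framed PET.
    Negative noisy values are retained (not clipped) for fitting realism.
    """
    if noise_scale < 0:
        raise ConfigurationError("noise_scale must be >= 0")
    if noise_scale == 0:
        return tac.with_activity(tac.activity.copy())
    rng = _rng(seed)
    sd = noise_scale * np.sqrt(
        np.maximum(tac.activity, NOISE_FLOOR_KBQ) / tac.schedule.duration_minutes
    )
    return tac.with_activity(tac.activity + rng.normal(0.0, 1.0, tac.activity.size) * sd)


#: documented plausible micro-parameter ranges for a reversible small-molecule
#: tracer; only V_T is externally constrained. The k4 floor keeps the bound
#: compartment equilibrating within the 90-min scan (half-time <= ~14 min),
#: the regime in which a 12.5-30 min Logan t* is meaningful.
K1_RANGE = (0.2, 0.8)
K3K4_RATIO_RANGE = (0.5, 4.0)
K4_RANGE = (0.05, 0.2)
K2_RANGE = (0.01, 2.0)


def rates_for_target_vt(target_vt: float, seed, v_b: float = 0.036,
                        max_tries: int = 200) -> KineticParams:
    """Sample plausible 2TCM micro-parameters with an exact target V_T.

    ``K1``, the ratio ``k3/k4`` and ``k4`` are drawn uniformly from the
    documented ranges, and ``k2`` is solved from
    ``(K1/k2) * (1 + k3/k4) = target_vt``. Combinations whose implied ``k2``
    falls outside its range are resampled.
    """
    if target_vt <= 0:
        raise ConfigurationError("target_vt must be positive")
    rng = _rng(seed)
    for _ in range(max_tries):
        k1 = rng.uniform(*K1_RANGE)
        ratio = rng.uniform(*K3K4_RATIO_RANGE)
        k4 = rng.uniform(*K4_RANGE)
        k2 = k1 * (1.0 + ratio) / target_vt
        if K2_RANGE[0] <= k2 <= K2_RANGE[1]:
            return KineticParams(k1, k2, ratio * k4, k4, v_b)
    raise ConfigurationError(
        f"target V_T {target_vt} not reachable within the documented rate ranges"
    )


def synth_tac(kp: KineticParams, params: InputFunctionParams,
              schedule: FrameSchedule | None = None, noise_scale: float = 0.0,
              seed=0, label: str = "") -> tuple[TimeActivityCurve, TimeActivityCurve]:
    """Forward-simulate one (tissue TAC, framed input TAC) pair."""
    schedule = schedule or study_frame_schedule()
    t = fine_time_grid(schedule)
    cp = input_function(params, t)
    ct = tissue_curve_2tcm(kp, cp, t)
    tac = frame_average(ct, t, schedule, label)
    inp = frame_average(cp, t, schedule, "input")
    if noise_scale > 0:
        tac = add_frame_noise(tac, noise_scale, seed)
    return tac, inp


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design configuration for the synthetic cohort.

    ``groups`` are (genotype, age_months) cells; ``vt_table`` holds the true
    group means and between-subject SDs; subjects with the same index and
    genotype share an identity across ages (longitudinal design).
    """

    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [(g, a) for g in GENOTYPES for a in AGES_MONTHS]
    )
    regions: tuple[str, ...] = REGIONS
    vt_table: pd.DataFrame = field(default_factory=default_vt_table)
    n_per_group: int = 20
    noise_scale: float = DEFAULT_NOISE_SCALE
    input_params: InputFunctionParams = field(default_factory=InputFunctionParams)
    schedule: FrameSchedule = field(default_factory=study_frame_schedule)
    seed: int = 0

    def group_truth(self, genotype: str, age: int, region: str) -> tuple[float, float]:
        tab = self.vt_table
        row = tab[(tab.genotype == genotype) & (tab.age_months == age) & (tab.region == region)]
        if row.empty:
            raise ConfigurationError(f"no truth for {genotype}/{age}M/{region}")
        return float(row.mean_vt.iloc[0]), float(row.sd_vt.iloc[0])


def default_cohort_config(genotype: str | None = None, age_months: int | None = None,
                          regions: tuple[str, ...] | None = None,
                          **overrides) -> CohortConfig:
    """The study-design cohort configuration, optionally restricted."""
    groups = [
        (g, a)
        for g in GENOTYPES for a in AGES_MONTHS
        if (genotype is None or g == genotype) and (age_months is None or a == age_months)
    ]
    cfg = CohortConfig(groups=groups, **overrides)
    if regions is not None:
        cfg.regions = tuple(regions)
    return cfg


@dataclass
class SubjectScan:
    subject: str
    genotype: str
    age_months: int
    tacs: dict[str, TimeActivityCurve]
    input_tac: TimeActivityCurve
    input_params: InputFunctionParams


@dataclass
class CohortData:
    scans: list[SubjectScan]
    truth: pd.DataFrame


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate noisy regional TACs plus a per-scan input function.

    Per subject and age, the true V_T of each region is drawn from
    Normal(group mean, group SD) truncated positive, converted to 2TCM rates
    with :func:`rates_for_target_vt`, forward-simulated, framed and
    noise-corrupted. Each scan shares a single bolus input across regions
    (amplitudes jittered ~5% between scans to mimic dose variation); the
    framed input is also noise-corrupted, as an extracted IDIF would be.
    Ground truth is returned as a tidy table.
    """
    rng = _rng(config.seed)
    t = fine_time_grid(config.schedule)
    scans: list[SubjectScan] = []
    rows = []
    for genotype, age in config.groups:
        for i in range(config.n_per_group):
            subject = f"{genotype}{i + 1:02d}"
            dose = rng.lognormal(0.0, 0.05)
            params = replace(
                config.input_params,
                A1=config.input_params.A1 * dose,
                A2=config.input_params.A2 * dose,
                A3=config.input_params.A3 * dose,
            )
            cp = input_function(params, t)
            inp = frame_average(cp, t, config.schedule, "input")
            inp = add_frame_noise(inp, 0.5 * config.noise_scale, rng)
            tacs = {}
            for region in config.regions:
                mean, sd = config.group_truth(genotype, age, region)
                true_vt = 0.0
                while true_vt <= 0.1:
                    true_vt = mean if sd == 0 else rng.normal(mean, sd)
                kp = rates_for_target_vt(true_vt, rng, v_b=0.0)
                ct = tissue_curve_2tcm(kp, cp, t)
                tac = frame_average(ct, t, config.schedule, region)
                tac = add_frame_noise(tac, config.noise_scale, rng)
                tacs[region] = tac
                rows.append({
                    "subject": subject, "genotype": genotype, "age_months": age,
                    "region": region, "true_vt": true_vt,
                    "K1": kp.K1, "k2": kp.k2, "k3": kp.k3, "k4": kp.k4,
                })
            scans.append(SubjectScan(subject, genotype, age, tacs, inp, params))
    return CohortData(scans, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# 4D phantom with a blood-pool blob
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and kinetics of the digital phantom.

    Regions are disjoint ellipsoids (center and semi-axes in voxels) on an
    isotropic grid; the left-ventricle blood pool carries the input-function
    activity and must admit the 3.5 mm IDIF sphere.
    """

    shape: tuple[int, int, int] = (40, 40, 30)
    voxel_size_mm: float = 0.776
    regions: dict[str, tuple[tuple[float, float, float], tuple[float, float, float], KineticParams]] = field(default_factory=dict)
    blood_pool_center: tuple[float, float, float] = (10.0, 10.0, 15.0)
    blood_pool_semiaxes: tuple[float, float, float] = (3.2, 3.2, 3.2)
    input_params: InputFunctionParams = field(default_factory=InputFunctionParams)
    schedule: FrameSchedule = field(default_factory=study_frame_schedule)
    voxel_noise_scale: float = 0.5

    BLOOD_LABEL = 99
    BLOOD_NAME = "blood_pool"


def default_phantom_spec(target_vts: dict[str, float] | None = None, seed=None,
                         **overrides) -> PhantomSpec:
    """Phantom with cerebellum / striatum / pons ellipsoids and a blood pool.

    Without a ``seed`` each region gets canonical well-conditioned kinetics
    (K1 = 0.5, k3/k4 = 2, k4 = 0.1, k2 solved for the target V_T) so the
    quantification examples are well-posed; with a ``seed`` the rates are
    sampled from the documented ranges instead (varied-kinetics cohorts).
    """
    if target_vts is None:
        target_vts = {"cerebellum": 6.61, "striatum": 4.49, "pons": 3.40}
    geoms = {
        "cerebellum": ((27.0, 27.0, 15.0), (7.0, 7.0, 6.0)),
        "striatum": ((27.0, 11.0, 15.0), (5.0, 5.0, 4.0)),
        "pons": ((11.0, 27.0, 15.0), (4.0, 4.0, 4.0)),
    }
    rng = _rng(seed) if seed is not None else None
    regions = {}
    for name, vt in target_vts.items():
        if name not in geoms:
            raise ConfigurationError(f"no default geometry for region {name!r}")
        center, semi = geoms[name]
        if rng is None:
            kp = KineticParams(0.5, 0.5 * 3.0 / vt, 0.2, 0.1, 0.0)
        else:
            kp = rates_for_target_vt(vt, rng, v_b=0.0)
        regions[name] = (center, semi, kp)
    return PhantomSpec(regions=regions, **overrides)


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grid = np.indices(shape, dtype=float)
    r2 = sum(((grid[d] - center[d]) / semiaxes[d]) ** 2 for d in range(3))
    return r2 <= 1.0


def generate_phantom_scan(spec: PhantomSpec, seed=0) -> tuple[DynamicImage, LabelAtlas, dict]:
    """Render a noisy 4D scan, its label atlas and the ground truth.

    Tissue-region voxels follow their frame-averaged 2TCM curves and
    blood-pool voxels the framed input function; zero-mean Gaussian voxel
    noise follows the same variance model as :func:`add_frame_noise`.
    """
    min_blood_mm = min(spec.blood_pool_semiaxes) * 2 * spec.voxel_size_mm
    if min_blood_mm < 3.5:
        raise ConfigurationError(
            f"blood pool ({min_blood_mm:.2f} mm across) cannot contain the 3.5 mm IDIF sphere"
        )
    rng = _rng(seed)
    t = fine_time_grid(spec.schedule)
    cp = input_function(spec.input_params, t)
    blood_tac = frame_average(cp, t, spec.schedule, "blood")

    labels = np.zeros(spec.shape, dtype=np.int16)
    names = {}
    data = np.zeros(spec.shape + (spec.schedule.n_frames,), dtype=np.float32)
    truth = {"input_params": spec.input_params, "input_tac": blood_tac, "regions": {}}

    masks = {}
    for idx, (name, (center, semi, kp)) in enumerate(sorted(spec.regions.items()), start=1):
        mask = _ellipsoid_mask(spec.shape, center, semi)
        masks[name] = (idx, mask)
    bp_mask = _ellipsoid_mask(spec.shape, spec.blood_pool_center, spec.blood_pool_semiaxes)
    masks[spec.BLOOD_NAME] = (spec.BLOOD_LABEL, bp_mask)
    taken = np.zeros(spec.shape, dtype=bool)
    for name, (idx, mask) in masks.items():
        if (mask & taken).any():
            raise ConfigurationError("phantom regions must be disjoint")
        taken |= mask

    for name, (idx, mask) in masks.items():
        if name == spec.BLOOD_NAME:
            tac = blood_tac
        else:
            kp = spec.regions[name][2]
            tac = frame_average(tissue_curve_2tcm(kp, cp, t), t, spec.schedule, name)
            truth["regions"][name] = {"params": kp, "true_vt": kp.vt, "tac": tac}
        labels[mask] = idx
        names[idx] = name
        data[mask, :] = tac.activity.astype(np.float32)

    if spec.voxel_noise_scale > 0:
        frame_min = spec.schedule.duration_minutes.astype(np.float32)
        sd = spec.voxel_noise_scale * np.sqrt(
            np.maximum(data, NOISE_FLOOR_KBQ, dtype=np.float32) / frame_min
        )
        data += rng.standard_normal(data.shape).astype(np.float32) * sd

    image = DynamicImage(data, spec.schedule, spec.voxel_size_mm)
    atlas = LabelAtlas(labels, names)
    return image, atlas, truth


# ---------------------------------------------------------------------------
# In-vitro section images (autoradiography + IHC)
# ---------------------------------------------------------------------------

#: documented synthetic tritium-standards curve: known activity (kBq/mg)
#: against measured 16-bit grey intensity, saturating at high activity
DEFAULT_STANDARDS = (
    (500.0, 0.0),
    (6000.0, 0.2),
    (14000.0, 0.5),
    (26000.0, 1.0),
    (42000.0, 2.0),
    (56000.0, 4.0),
    (62000.0, 6.0),
)

#: nonspecific-binding activity floor, kBq/mg
DEFAULT_NB_ACTIVITY = 0.4
#: tritiated-ligand molar activity, GBq/umol
DEFAULT_MOLAR_ACTIVITY = 2.66


def _activity_to_grey(activity: np.ndarray, standards) -> np.ndarray:
    grey = np.array([g for g, _ in standards])
    act = np.array([a for _, a in standards])
    return np.interp(activity, act, grey)


def generate_section_images(
    true_density_map: dict[str, float],
    standards=DEFAULT_STANDARDS,
    seed=0,
    ihc_positive_fraction: dict[str, float] | None = None,
    molar_activity: float = DEFAULT_MOLAR_ACTIVITY,
    nb_activity: float = DEFAULT_NB_ACTIVITY,
    roi_size: int = 40,
    grey_noise_sd: float = 150.0,
    ihc_threshold: int = 170,
) -> dict:
    """Render synthetic total-binding / nonspecific-binding autoradiograms,
    an 8-bit IHC section and the ROI label mask.

    Each ROI (``roi_size`` x ``roi_size`` pixels, tiled on the section) has a
    planted specific density in pmol/mg. Specific density converts to
    activity through the molar activity (pmol/mg x GBq/umol = kBq/mg); total
    binding adds the nonspecific floor, which is all the NB image carries.
    Grey values come from inverting the standards curve, with mild Gaussian
    grey noise confined so ROI means stay on the local linear segment. The
    IHC image plants an exact fraction of at-or-below-threshold (DAB-dark)
    pixels per ROI.
    """
    if any(d < 0 for d in true_density_map.values()):
        raise ConfigurationError("specific densities must be non-negative")
    rng = _rng(seed)
    names = list(true_density_map)
    n = len(names)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    pad = 6
    shape = (nrow * (roi_size + pad) + pad, ncol * (roi_size + pad) + pad)

    rois = np.zeros(shape, dtype=np.int16)
    nb_grey = float(_activity_to_grey(np.array([nb_activity]), standards)[0])
    tb_img = np.full(shape, nb_grey)
    nb_img = np.full(shape, nb_grey)
    ihc = np.full(shape, 255, dtype=np.uint8)
    roi_names = {}

    for k, name in enumerate(names):
        r, c = divmod(k, ncol)
        sl = (slice(pad + r * (roi_size + pad), pad + r * (roi_size + pad) + roi_size),
              slice(pad + c * (roi_size + pad), pad + c * (roi_size + pad) + roi_size))
        rois[sl] = k + 1
        roi_names[k + 1] = name
        tb_act = true_density_map[name] * molar_activity + nb_activity
        tb_img[sl] = _activity_to_grey(np.array([tb_act]), standards)[0]
        npix = roi_size * roi_size
        frac = 0.0 if ihc_positive_fraction is None else ihc_positive_fraction.get(name, 0.0)
        npos = int(round(frac * npix))
        vals = np.concatenate([
            rng.integers(60, ihc_threshold + 1, npos),
            rng.integers(ihc_threshold + 1, 251, npix - npos),
        ])
        rng.shuffle(vals)
        ihc[sl] = vals.reshape(roi_size, roi_size).astype(np.uint8)

    for img in (tb_img, nb_img):
        img += rng.normal(0.0, grey_noise_sd, shape)
    tb16 = np.clip(np.round(tb_img), 0, 65535).astype(np.uint16)
    nb16 = np.clip(np.round(nb_img), 0, 65535).astype(np.uint16)
    return {
        "tb": tb16,
        "nb": nb16,
        "ihc": ihc,
        "rois": rois,
        "roi_names": roi_names,
        "standards": tuple(standards),
        "molar_activity": molar_activity,
        "nb_activity": nb_activity,
    }
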