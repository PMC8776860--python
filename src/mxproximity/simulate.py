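"""Synthetic slide point patterns and survival cohorts with known ground truth.

The generators emulate the two data layers the pipeline consumes:

* slide-level marked point patterns — reference (CD8-like) cells as a
  homogeneous Poisson process, target (SOX10-like) cells as a mixture of a
  uniform component and an "attraction" component displaced from randomly
  chosen reference cells by an isotropic Gaussian, plus unlabeled nucleated
  background cells;
* paired pre/post cohorts in which the programmed log2 expansion of the
  target-cell intensity is monotonically linked to progression-free
  survival, the direction observed clinically (faster progression goes with
  greater tumor-cell expansion);
* survival cohorts with exponential event times under a proportional-hazards
  model and independent exponential censoring, carrying the covariates of
  the TCGA-style analysis (immune score, marker z-scores, CD8A expression,
  stage, sex).

Every generator is deterministic given its seed; a single integer seed
drives named substreams so that per-patient pieces are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .io import CohortTable, PatientPairRecord, SlideCellTable

_SIM_PANEL: tuple[str, ...] = ("SOX10", "CD8")


@dataclass(frozen=True)
class SlideSimConfig:
    """Marked point pattern for a single slide.

    Intensities are in cells per square micrometre (2e-4 /um^2 == 200 /mm^2).
    ``attract_frac`` of the target cells are placed as Gaussian displacements
    (scale ``attract_sigma_um``) from uniformly chosen reference cells; the
    remainder are uniform. ``torus`` boundary wraps coordinates so that
    closed-form pairing probabilities hold exactly; ``bounded`` clips.
    """

    width_um: float = 1000.0
    height_um: float = 1000.0
    lambda_ref: float = 2e-4
    lambda_target: float = 3e-4
    attract_frac: float = 0.0
    attract_sigma_um: float = 20.0
    lambda_other: float = 1.5e-3
    boundary: str = "torus"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ConfigError("slide dimensions must be positive")
        for name in ("lambda_ref", "lambda_target", "lambda_other"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.attract_frac <= 1.0:
            raise ConfigError("attract_frac must lie in [0, 1]")
        if self.attract_sigma_um <= 0:
            raise ConfigError("attract_sigma_um must be > 0")
        if self.boundary not in ("torus", "bounded"):
            raise ConfigError(f"unknown boundary mode {self.boundary!r}")
        if self.lambda_ref == 0 and self.attract_frac > 0:
            raise ConfigError(
                "attraction requires reference cells (lambda_ref > 0)"
            )

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um


@dataclass(frozen=True)
class CohortSimConfig:
    """Paired pre/post cohort with a programmed expansion-PFS link.

    Per patient, PFS is uniform on ``pfs_range_months`` and the post-slide
    target intensity is ``pre * 2**(slope * z(-PFS) + noise)`` where ``z``
    standardizes over the cohort, so ``slope > 0`` always encodes "shorter
    PFS, greater tumor-cell expansion".
    """

    n_patients: int = 11
    baseline: SlideSimConfig = field(default_factory=SlideSimConfig)
    slope: float = 1.2
    noise_sd: float = 0.4
    pfs_range_months: tuple[float, float] = (1.5, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        lo, hi = self.pfs_range_months
        if not lo < hi:
            raise ConfigError("pfs_range_months must satisfy min < max")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


#: Default covariate distributions for the survival generator, echoing the
#: scale of the TCGA-style cohort: standardized marker z-scores, a
#: standardized immune score, log2 CD8A expression, and male fraction.
DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, tuple] = {
    "immune_score": ("normal", 0.0, 1.0),
    "sox10_z": ("normal", 0.0, 1.0),
    "mlana_z": ("normal", 0.0, 1.0),
    "log2_cd8a": ("normal", 3.0, 1.5),
    "sex_male": ("bernoulli", 0.6),
}

#: Default log-hazard coefficients: protective immune infiltration, adverse
#: tumor-cellularity markers, higher late-stage hazard.
DEFAULT_BETAS: dict[str, float] = {
    "immune_score": -0.55,
    "sox10_z": 0.20,
    "mlana_z": 0.15,
    "stage_late": 0.9,
}


@dataclass(frozen=True)
class SurvSimConfig:
    """Proportional-hazards survival cohort.

    Event times are exponential with hazard
    ``baseline_hazard * exp(sum_k beta_k x_k)`` (per month); censoring times
    are independent exponentials with rate ``censor_rate``. ``stage_mix`` is
    the early-stage fraction; a ``stage_late`` indicator is always available
    to ``betas``. Defaults size the cohort like the melanoma reference
    cohort (n=445, roughly balanced early/late, median OS of a few years).
    """

    n: int = 445
    betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))
    baseline_hazard: float = 0.012
    censor_rate: float = 0.010
    covariate_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTRIBUTIONS))
    stage_mix: float = 0.53
    interaction: tuple[str, str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ConfigError("n must be >= 10")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if not 0.0 <= self.stage_mix <= 1.0:
            raise ConfigError("stage_mix must lie in [0, 1]")
        known = set(self.covariate_distributions) | {"stage_late"}
        undeclared = set(self.betas) - known
        if undeclared:
            raise ConfigError(
                f"betas reference undeclared covariates {sorted(undeclared)}"
            )


# ---------------------------------------------------------------------------
# slide simulation
# ---------------------------------------------------------------------------

def _uniform_points(rng, n, w, h):
    return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])


def simulate_slide(cfg: SlideSimConfig, slide_id: str = "sim") -> SlideCellTable:
    """Draw one slide from the marked point process.

    Reference and unlabeled counts are Poisson at their intensities over the
    window; target cells split binomially into attracted and uniform
    components. All cells are nucleated.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    w, h, area = cfg.width_um, cfg.height_um, cfg.area_um2

    ref = _uniform_points(rng, rng.poisson(cfg.lambda_ref * area), w, h)
    n_target = rng.poisson(cfg.lambda_target * area)
    n_attr = rng.binomial(n_target, cfg.attract_frac) if n_target else 0

    if n_attr and len(ref) == 0:
        # Poisson draw produced no anchors; degrade gracefully to uniform.
        n_attr = 0
    anchors = ref[rng.integers(0, len(ref), n_attr)] if n_attr else np.empty((0, 2))
    attracted = anchors + rng.normal(0.0, cfg.attract_sigma_um, (n_attr, 2))
    if cfg.boundary == "torus":
        attracted = np.mod(attracted, [w, h])
    else:
        attracted = np.clip(attracted, [0, 0], [w, h])
    uniform_targets = _uniform_points(rng, n_target - n_attr, w, h)
    target = np.vstack([attracted, uniform_targets])

    other = _uniform_points(rng, rng.poisson(cfg.lambda_other * area), w, h)

    def block(prefix, pts, sox10, cd8):
        n = len(pts)
        return pd.DataFrame({
            "cell_id": [f"{prefix}{i:06d}" for i in range(n)],
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "nucleated": np.ones(n, dtype=bool),
            "SOX10": np.full(n, sox10),
            "CD8": np.full(n, cd8),
        })

    cells = pd.concat(
        [block("t", target, True, False),
         block("r", ref, False, True),
         block("o", other, False, False)],
        ignore_index=True,
    )
    return SlideCellTable(slide_id, cells, _SIM_PANEL,
                          region_area_mm2=area / 1e6)


# ---------------------------------------------------------------------------
# paired pre/post cohort
# ---------------------------------------------------------------------------

def simulate_paired_cohort(cfg: CohortSimConfig):
    """Simulate a pre/post slide pair per patient.

    Returns ``(slides, clinical, truth)`` where ``slides`` maps slide ids to
    tables, ``clinical`` is the list of patient linkage records and
    ``truth`` maps patient ids to the programmed log2 fold-change of the
    target intensity (the quantity the pipeline should recover).
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_pfs, ss_noise, *ss_slides = root.spawn(2 + 2 * cfg.n_patients)
    rng_pfs = np.random.default_rng(ss_pfs)
    rng_noise = np.random.default_rng(ss_noise)

    lo, hi = cfg.pfs_range_months
    pfs = rng_pfs.uniform(lo, hi, cfg.n_patients)
    neg = -pfs
    z = (neg - neg.mean()) / (neg.std(ddof=0) or 1.0)
    log2_fc = cfg.slope * z + rng_noise.normal(0.0, cfg.noise_sd, cfg.n_patients)

    slides: dict[str, SlideCellTable] = {}
    clinical: list[PatientPairRecord] = []
    truth: dict[str, float] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        pre_id, post_id = f"{pid}-pre", f"{pid}-post"
        pre_cfg = replace(cfg.baseline,
                          seed=int(ss_slides[2 * i].generate_state(1)[0] >> 1))
        post_cfg = replace(
            cfg.baseline,
            lambda_target=cfg.baseline.lambda_target * 2.0 ** log2_fc[i],
            seed=int(ss_slides[2 * i + 1].generate_state(1)[0] >> 1),
        )
        slides[pre_id] = simulate_slide(pre_cfg, pre_id)
        slides[post_id] = simulate_slide(post_cfg, post_id)
        clinical.append(PatientPairRecord(
            patient_id=pid, pre_slide_id=pre_id, post_slide_id=post_id,
            pfs_months=float(pfs[i]), progression_event=True,
        ))
        truth[pid] = float(log2_fc[i])
    return slides, clinical, truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def _draw(rng, spec, n):
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], n)
    if kind == "lognormal":
        return rng.lognormal(spec[1], spec[2], n)
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], n)
    if kind == "bernoulli":
        return rng.binomial(1, spec[1], n).astype(float)
    raise ConfigError(f"unknown covariate distribution {spec!r}")


def simulate_survival_cohort(cfg: SurvSimConfig) -> CohortTable:
    """Draw a cohort table under the configured proportional-hazards model."""
    root = np.random.SeedSequence(cfg.seed)
    rng_x, rng_t, rng_c, rng_g = (np.random.default_rng(s) for s in root.spawn(4))

    x = {name: _draw(rng_x, spec, cfg.n)
         for name, spec in cfg.covariate_distributions.items()}
    x["stage_late"] = (rng_x.uniform(size=cfg.n) >= cfg.stage_mix).astype(float)

    log_hr = np.zeros(cfg.n)
    for name, beta in cfg.betas.items():
        log_hr += beta * x[name]
    if cfg.interaction is not None:
        a, b, beta = cfg.interaction
        log_hr += beta * x[a] * x[b]
    hazard = cfg.baseline_hazard * np.exp(log_hr)

    t_event = rng_t.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        t_censor = rng_c.exponential(1.0 / cfg.censor_rate, cfg.n)
    else:
        t_censor = np.full(cfg.n, np.inf)
    os_months = np.minimum(t_event, t_censor)
    os_event = t_event <= t_censor

    log2_cd8a = x.get("log2_cd8a", np.full(cfg.n, 3.0))
    sox10 = x.get("sox10_z", np.zeros(cfg.n))
    df = pd.DataFrame({
        "patient_id": [f"S{i + 1:04d}" for i in range(cfg.n)],
        "os_months": os_months,
        "os_event": os_event,
        "stage_group": np.where(x["stage_late"] > 0, "late", "early"),
        "sex": np.where(x.get("sex_male", np.zeros(cfg.n)) > 0,
                        "Male", "Female"),
        "immune_score": x.get("immune_score", np.zeros(cfg.n)),
        "sox10_z": sox10,
        "mlana_z": x.get("mlana_z", np.zeros(cfg.n)),
        "cd8a_expr": 2.0 ** log2_cd8a,
    })
    # Downstream response genes track CD8A positively and tumor-marker level
    # negatively, with a mild negative interaction, on the log2 scale.
    gene_cols = []
    for g, (b0, b_cd8, b_sox, b_int, sd) in {
        "PDCD1": (0.5, 0.8, -0.05, 0.0, 0.6),
        "CD274": (0.8, 0.7, -0.05, 0.0, 0.6),
        "IFNG": (0.2, 0.9, -0.25, -0.08, 0.7),
        "GZMB": (0.4, 0.9, -0.15, -0.05, 0.7),
    }.items():
        log2_g = (b0 + b_cd8 * log2_cd8a + b_sox * sox10
                  + b_int * sox10 * log2_cd8a + rng_g.normal(0, sd, cfg.n))
        col = f"expr_{g}"
        df[col] = 2.0 ** log2_g
        gene_cols.append(col)
    # custom covariates beyond the standard schema ride along by name so
    # that recovery analyses can reach them
    standard = {"immune_score", "sox10_z", "mlana_z", "log2_cd8a", "sex_male"}
    for name in cfg.covariate_distributions:
        if name not in standard:
            df[name] = x[name]
    return CohortTable(df, tuple(gene_cols))


def expected_paired_fraction(lambda_ref: float, radius_um: float) -> float:
    """Poisson void probability: the chance a target cell has at least one
    reference cell within ``radius_um`` under a homogeneous reference process
    on a torus, ``1 - exp(-lambda * pi * r^2)``."""
    return 1.0 - math.exp(-lambda_ref * math.pi * radius_um ** 2)
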