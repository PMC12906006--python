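"""Seeded generators for ground-truthed benchmark inputs.

The study design the benchmark assumes: two bulk cohorts that share the
same disease contrast and the same underlying composition shifts (cohorts
sample the same biology), plus an scRNA-seq cohort whose annotations give
per-sample ground-truth proportions, plus survival driven by planted
prognostic cell types. Concretely:

* Sample compositions are Dirichlet draws. Condition 2 multiplies the
  concentration of each planted DP cell type by an effect factor, so both
  cohorts shift in the same direction by construction; a per-cohort
  log-normal jitter on the concentrations emulates batch effects without
  flipping directions.
* Deconvolution methods are emulated by corrupting the true matrix:
  additive Gaussian noise and bias on the logit scale (keeps estimates in
  (0,1)), optional per-cell-type zero-inflation (the "assigns zero to most
  samples" failure class), then row renormalization.
* scRNA annotations are multinomial cell draws from each sample's true
  composition.
* Survival: exponential event times with hazard h0 * exp(sum beta_t *
  z(proportion_t)); uniform censoring with the window tuned by bisection
  to a target event count.

Every generator is a pure function of (parameters, seed): the same seed
reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from dpbench.io import (
    CellAnnotationTable,
    CohortBundle,
    ProportionMatrix,
    SurvivalTable,
)

__all__ = [
    "SyntheticTruth",
    "MethodErrorModel",
    "default_truth",
    "method_presets",
    "simulate_cohort_pair",
    "simulate_scrna_annotations",
    "emulate_method",
    "simulate_survival",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth and generator parameters.

    cell_types / base_alpha
        Dirichlet concentrations per cell type; their relative sizes set
        the mean composition, their sum the between-sample variability.
    dp_effects
        cell type -> multiplicative factor applied to its concentration in
        condition 2 (shared by both cohorts). Factor > 1 means the type is
        more abundant in condition 2.
    batch_sd
        s.d. of the per-cohort log-normal jitter on concentrations.
    pr_betas
        cell type -> log-hazard coefficient per SD of proportion.
    baseline_hazard
        h0 of the exponential event-time model (per unit time).
    seed
        Root seed; all randomness derives from it.
    """

    cell_types: Sequence[str]
    base_alpha: Sequence[float]
    dp_effects: dict = field(default_factory=dict)
    batch_sd: float = 0.1
    pr_betas: dict = field(default_factory=dict)
    baseline_hazard: float = 0.1
    condition_names: tuple = ("condition1", "condition2")
    seed: int = 0

    def __post_init__(self):
        if len(self.cell_types) != len(self.base_alpha):
            raise ValueError("cell_types and base_alpha lengths differ")
        if any(a <= 0 for a in self.base_alpha):
            raise ValueError("all Dirichlet concentrations must be > 0")
        unknown = set(self.dp_effects) - set(self.cell_types)
        if unknown:
            raise ValueError(f"dp_effects for unknown cell types: {unknown}")
        unknown = set(self.pr_betas) - set(self.cell_types)
        if unknown:
            raise ValueError(f"pr_betas for unknown cell types: {unknown}")

    @property
    def planted_dp_directions(self) -> dict:
        """cell type -> expected sign(median_cond1 - median_cond2)."""
        return {
            ct: (-1 if f > 1 else (1 if f < 1 else 0))
            for ct, f in self.dp_effects.items()
            if f != 1
        }

    def with_seed(self, seed: int) -> "SyntheticTruth":
        return replace(self, seed=seed)


@dataclass
class MethodErrorModel:
    """Estimation-error profile of an emulated deconvolution method."""

    name: str = "emulated"
    logit_noise_sd: float = 0.3
    bias: dict = field(default_factory=dict)  # cell type -> additive logit shift
    zero_inflation: dict = field(default_factory=dict)  # cell type -> P(force 0)

    def __post_init__(self):
        for ct, z in self.zero_inflation.items():
            if not 0 <= z <= 1:
                raise ValueError(f"zero_inflation[{ct!r}] must be in [0, 1]")


#: Default study conditions: 15 cell types spanning abundant (~20%) to rare
#: (~1%), two planted DP effects (one 3x up in condition 2, one 3x down),
#: one planted prognostic type with an adverse per-SD log-hazard of 1.2,
#: 50 samples per condition per cohort (set at call sites). The planted
#: effects are balanced — 3 x 2.0 up on ct08 offsets 6.0 / 3 down on ct02 —
#: so the concentration total is unchanged and every non-planted type keeps
#: an identical marginal distribution in both conditions (exactly null).
_DEFAULT_ALPHAS = [8.0, 6.0, 5.0, 4.0, 3.0, 3.0, 2.5, 2.0, 1.5, 1.2, 1.0, 0.8, 0.6, 0.5, 0.4]


def default_truth(seed: int = 0) -> SyntheticTruth:
    k = len(_DEFAULT_ALPHAS)
    cell_types = [f"ct{i:02d}" for i in range(1, k + 1)]
    return SyntheticTruth(
        cell_types=cell_types,
        base_alpha=_DEFAULT_ALPHAS,
        dp_effects={"ct08": 3.0, "ct02": 1 / 3.0},
        batch_sd=0.1,
        pr_betas={"ct06": 1.2},
        seed=seed,
    )


def method_presets(noise_scale: float = 1.0) -> list[MethodErrorModel]:
    """Three emulated method classes: accurate, noisy, zero-inflating.

    ``noise_scale`` multiplies every corruption (0 -> perfect recovery),
    which is what noise-grid experiments sweep.
    """
    s = noise_scale
    return [
        MethodErrorModel(name="accurate", logit_noise_sd=0.15 * s),
        MethodErrorModel(name="noisy", logit_noise_sd=0.8 * s),
        # zeroes out one planted DP type and one rare type in most samples,
        # the failure class seen in real methods on NK cells
        MethodErrorModel(
            name="zero_inflating",
            logit_noise_sd=0.4 * s,
            zero_inflation={"ct08": min(0.8 * s, 1.0), "ct15": min(0.8 * s, 1.0)},
        ),
    ]


def _cohort_alpha(truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    jitter = np.exp(rng.normal(0.0, truth.batch_sd, size=len(truth.cell_types)))
    return np.asarray(truth.base_alpha, dtype=float) * jitter


def _condition_alphas(truth: SyntheticTruth, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    effects = np.array([truth.dp_effects.get(ct, 1.0) for ct in truth.cell_types])
    return alpha, alpha * effects


def _draw_condition(
    rng: np.random.Generator,
    alpha: np.ndarray,
    n: int,
    prefix: str,
    condition: str,
    truth: SyntheticTruth,
) -> tuple[pd.DataFrame, dict]:
    props = rng.dirichlet(alpha, size=n)
    ids = [f"{prefix}_{condition}_s{i:03d}" for i in range(1, n + 1)]
    df = pd.DataFrame(props, index=ids, columns=list(truth.cell_types))
    return df, {sid: condition for sid in ids}


def simulate_cohort_pair(
    truth: SyntheticTruth,
    n_per_condition: int = 50,
    cohort_names: tuple = ("cohortA", "cohortB"),
) -> tuple[CohortBundle, CohortBundle, dict]:
    """Two bulk cohorts sharing the planted condition-2 composition shifts.

    Returns the cohorts (ground-truth proportion matrices, no survival) and
    a truth record with the planted DP directions.
    """
    if n_per_condition < 3:
        raise ValueError("need at least 3 samples per condition")
    rng = np.random.default_rng(truth.seed)
    bundles = []
    for name in cohort_names:
        alpha = _cohort_alpha(truth, rng)
        a1, a2 = _condition_alphas(truth, alpha)
        c1, c2 = truth.condition_names
        df1, cond1 = _draw_condition(rng, a1, n_per_condition, name, c1, truth)
        df2, cond2 = _draw_condition(rng, a2, n_per_condition, name, c2, truth)
        values = pd.concat([df1, df2])
        pm = ProportionMatrix(values, {**cond1, **cond2}, source="deconvolution:truth")
        bundles.append(CohortBundle(name=name, proportions=pm, platform="rnaseq"))
    record = {
        "planted_dp": truth.planted_dp_directions,
        "pr_betas": dict(truth.pr_betas),
        "seed": truth.seed,
        "n_per_condition": n_per_condition,
    }
    return bundles[0], bundles[1], record


def simulate_scrna_annotations(
    truth: SyntheticTruth,
    n_samples: int = 12,
    cells_per_sample: int = 1000,
) -> CellAnnotationTable:
    """Multinomial single-cell annotations for ``n_samples`` per condition.

    Per sample, true proportions are drawn like a cohort's, then
    ``cells_per_sample`` cells are sampled multinomially and recorded as
    (cell_id, sample_id, condition, cell_type) rows. Tallying the table
    recovers the truth up to multinomial error.
    """
    if cells_per_sample < 50:
        raise ValueError("cells_per_sample must be >= 50")
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))
    alpha = _cohort_alpha(truth, rng)
    a1, a2 = _condition_alphas(truth, alpha)
    rows = []
    cell_counter = 0
    for condition, a in zip(truth.condition_names, (a1, a2)):
        for i in range(1, n_samples + 1):
            sid = f"sc_{condition}_s{i:03d}"
            p = rng.dirichlet(a)
            counts = rng.multinomial(cells_per_sample, p)
            for ct, c in zip(truth.cell_types, counts):
                for _ in range(int(c)):
                    cell_counter += 1
                    rows.append((f"cell{cell_counter:07d}", sid, condition, ct))
    df = pd.DataFrame(rows, columns=["cell_id", "sample_id", "condition", "cell_type"])
    return CellAnnotationTable(df)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def emulate_method(
    true_pm: ProportionMatrix,
    err: MethodErrorModel,
    seed: int = 0,
) -> ProportionMatrix:
    """Corrupt a ground-truth matrix into an emulated method estimate.

    Logit-scale Gaussian noise and per-cell-type bias, then per-cell-type
    zero-inflation, then row renormalization. A zero mask wiping out an
    entire sample is redrawn for that sample. With a zero-noise model the
    output equals the input.
    """
    rng = np.random.default_rng(seed)
    vals = true_pm.values.to_numpy(copy=True)
    n, k = vals.shape
    cts = true_pm.cell_types
    if err.logit_noise_sd > 0 or err.bias:
        eps = np.clip(vals, 1e-12, 1 - 1e-12)
        shift = np.array([err.bias.get(ct, 0.0) for ct in cts])
        noisy = _logit(eps) + shift
        if err.logit_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, err.logit_noise_sd, size=(n, k))
        vals = _expit(noisy)
    if err.zero_inflation:
        zp = np.array([err.zero_inflation.get(ct, 0.0) for ct in cts])
        mask = rng.random((n, k)) < zp
        dead = mask.all(axis=1)
        while dead.any():  # a sample with every type zeroed is unusable
            mask[dead] = rng.random((int(dead.sum()), k)) < zp
            dead = mask.all(axis=1)
        vals = np.where(mask, 0.0, vals)
    vals = vals / vals.sum(axis=1, keepdims=True)
    out = pd.DataFrame(vals, index=true_pm.values.index, columns=cts)
    return ProportionMatrix(
        out, true_pm.condition_of, source=f"deconvolution:{err.name}"
    )


def simulate_survival(
    pm: ProportionMatrix,
    truth: SyntheticTruth,
    target_events: Optional[tuple[int, int]] = None,
    seed: Optional[int] = None,
) -> SurvivalTable:
    """Survival linked to the planted prognostic cell types.

    hazard_i = h0 * exp(sum_t beta_t * z(proportion_it)) with z the
    within-matrix standardization; event times are exponential and
    censoring times uniform on (0, c_max], with c_max tuned by bisection so
    the event count lands in ``target_events`` (default: 65-75% of n,
    i.e. roughly 30% censoring). If the top of the range is unreachable a
    warning reports the achieved count.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 11])
    )
    n = len(pm.samples)
    if target_events is None:
        target_events = (int(0.65 * n), int(0.75 * n))
    lo, hi = target_events
    z = np.zeros(n)
    for ct, beta in truth.pr_betas.items():
        x = pm.column(ct).to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd > 0:
            z = z + beta * (x - x.mean()) / sd
    hazard = truth.baseline_hazard * np.exp(z)
    t_event = rng.exponential(1.0 / hazard)
    u = rng.random(n)

    def n_events(c_max: float) -> int:
        return int((t_event <= u * c_max).sum())

    c_low, c_high = 1e-6, float(t_event.max() / max(u.min(), 1e-12)) + 1.0
    if n_events(c_high) < lo:
        import warnings

        warnings.warn(
            f"event target {target_events} unreachable; achieved {n_events(c_high)}"
        )
        c_max = c_high
    else:
        for _ in range(200):
            mid = 0.5 * (c_low + c_high)
            ne = n_events(mid)
            if lo <= ne <= hi:
                c_low = c_high = mid
                break
            if ne < lo:
                c_low = mid
            else:
                c_high = mid
        c_max = 0.5 * (c_low + c_high)
    censor = u * c_max
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return SurvivalTable(
        pd.DataFrame({"sample_id": pm.samples, "time": time, "event": event})
    )
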