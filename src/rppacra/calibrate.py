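"""Patient-specific calibration by conditional robustness.

The four most divergent model proteins (two higher in the short-survival
patient, two lower) serve as evaluation functions.  Hypercube sampling of
the full parameter space induces, through the joint directional tails of
their AUC distributions, an "s-OS-like" and an "l-OS-like" conditioned
draw set.  Parameters whose conditional densities differ most (high MIRI)
are the ones that can move the network between the two phenotypes; those
above the upper boxplot fence of the MIRI distribution are fixed -- to the
median of their s-OS-like conditioned draws in the s-OS model and of the
opposite tail in the l-OS model -- yielding two personalized models that
share the remaining free parameter space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import PathwayModel
from .robustness import (
    DEFAULT_ALPHA,
    MIN_TAIL_SAMPLES,
    ParameterSpace,
    SampleSet,
    TailSpec,
    miri_for_columns,
    run_sampling,
    select_joint_tail,
)
from .rppa import DivergenceSelection

log = logging.getLogger(__name__)

S_OS = "s-OS"
L_OS = "l-OS"


@dataclass(frozen=True)
class CalibrationConfig:
    """Sampling sizes for the calibration stage.

    Reference scale is 100000 samples x 10 realizations; the desk-scale
    defaults (5000 x 3) keep a full run on one CPU in minutes and are the
    documented scaled-down setting.
    """

    n_samples: int = 5000
    realizations: int = 3
    alpha: float = DEFAULT_ALPHA
    threshold_rule: str = "boxplot-fence"      # or "fixed-value"
    fixed_cutoff: float | None = None
    seed: int = 0
    horizon: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.realizations < 1:
            raise ValueError("counts must be >= 1")
        if self.threshold_rule not in ("boxplot-fence", "fixed-value"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_rule == "fixed-value" and self.fixed_cutoff is None:
            raise ValueError("fixed-value rule needs fixed_cutoff")


@dataclass
class CalibrationResult:
    miri_mean: pd.Series               # per free parameter
    miri_sd: pd.Series
    per_realization: pd.DataFrame      # realizations x parameters
    tail_draws: dict[str, pd.DataFrame]  # patient label -> conditioned draws
    fallback_used: bool
    n_failed: int
    config: CalibrationConfig


@dataclass
class PatientModel:
    """A pathway model with high-MIRI parameters pinned to one patient's tail."""

    patient_label: str
    model: PathwayModel
    fixed_params: dict[str, float]
    free_params: list[str]

    def __post_init__(self) -> None:
        if self.patient_label not in (S_OS, L_OS):
            raise ValueError(f"patient label must be {S_OS!r} or {L_OS!r}")
        all_names = set(self.model.parameter_names)
        if set(self.fixed_params) | set(self.free_params) != all_names:
            raise ValueError("fixed and free parameters must partition the space")
        if set(self.fixed_params) & set(self.free_params):
            raise ValueError("fixed and free parameters overlap")

    def space(self, log10_bounds=(-2.0, 2.0)) -> ParameterSpace:
        return ParameterSpace.from_model(
            self.model, log10_bounds=log10_bounds, fixed=self.fixed_params
        )


def _tail_spec(selection: DivergenceSelection, alpha: float) -> TailSpec:
    if not selection.calibration_proteins:
        raise ValueError("selection carries no calibration proteins")
    directions = {
        node: ("upper" if sign > 0 else "lower")
        for node, sign in selection.calibration_proteins.items()
    }
    return TailSpec(alpha=alpha, directions=directions)


def run_calibration(
    model: PathwayModel,
    space: ParameterSpace,
    selection: DivergenceSelection,
    cfg: CalibrationConfig,
) -> CalibrationResult:
    """CRA over the full space against the four calibration proteins.

    Per realization: hypercube sample -> simulate -> AUC of the calibration
    proteins -> joint directional tails -> MIRI per free parameter
    (null-corrected, on log10 draws).  Conditioned draws are pooled over
    realizations for the later parameter fixing.
    """
    spec = _tail_spec(selection, cfg.alpha)
    eval_nodes = list(spec.directions)
    for node in eval_nodes:
        if node not in model.node_index:
            raise KeyError(f"calibration protein {node!r} not in model")
    free = space.free_names
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.realizations)
    rows = []
    s_tails, l_tails = [], []
    fallback_any = False
    n_failed = 0
    for r in range(cfg.realizations):
        sub_seed = int(seeds[r].generate_state(1)[0] % (2**31 - 1))
        samples: SampleSet = run_sampling(
            model, space, eval_nodes, cfg.n_samples, sub_seed,
            realization_id=r, horizon=cfg.horizon,
        )
        n_failed += samples.n_failed
        s_idx, l_idx, fallback = select_joint_tail(
            samples, spec, min_size=MIN_TAIL_SAMPLES
        )
        fallback_any |= fallback
        rows.append(
            miri_for_columns(samples.draws, l_idx, s_idx, free, rng=sub_seed)
        )
        s_tails.append(samples.draws.iloc[s_idx])
        l_tails.append(samples.draws.iloc[l_idx])
    per_real = pd.DataFrame(rows)
    sd = per_real.std(ddof=1) if cfg.realizations > 1 else per_real.iloc[0] * 0.0
    return CalibrationResult(
        miri_mean=per_real.mean(),
        miri_sd=sd,
        per_realization=per_real,
        tail_draws={S_OS: pd.concat(s_tails), L_OS: pd.concat(l_tails)},
        fallback_used=fallback_any,
        n_failed=n_failed,
        config=cfg,
    )


def threshold_parameters(
    miri: pd.Series,
    rule: str = "boxplot-fence",
    cutoff: float | None = None,
) -> list[str]:
    """Select high-MIRI parameters.

    ``boxplot-fence``: MIRI > Q3 + 1.5 IQR of the MIRI distribution (the
    upper outlier fence of the calibration box plot).  ``fixed-value``: an
    explicit cutoff.  An empty selection is returned with a warning.
    """
    if len(miri) < 4:
        raise ValueError("need at least 4 parameters to threshold")
    if rule == "boxplot-fence":
        q1, q3 = np.percentile(miri.to_numpy(), [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
    elif rule == "fixed-value":
        if cutoff is None:
            raise ValueError("fixed-value rule needs a cutoff")
        fence = cutoff
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    selected = [name for name, v in miri.items() if v > fence]
    if not selected:
        log.warning("threshold rule %r selected no parameters (fence=%.3f)",
                    rule, fence)
    return selected


def fix_patient_parameters(
    model: PathwayModel,
    selected: list[str],
    tails: Mapping[str, pd.DataFrame],
    patient: str,
) -> PatientModel:
    """Pin the selected parameters to the median of the patient's tail draws.

    The s-OS model uses the s-OS-like conditioned samples, the l-OS model
    the opposite tail, so swapping the patient label swaps the fixed
    values exactly.
    """
    if patient not in (S_OS, L_OS):
        raise ValueError(f"patient must be {S_OS!r} or {L_OS!r}")
    if not selected:
        log.warning("empty selection: %s model keeps all parameters free", patient)
        return PatientModel(
            patient_label=patient, model=model, fixed_params={},
            free_params=list(model.parameter_names),
        )
    if patient not in tails:
        raise KeyError(f"no conditioned samples for patient {patient!r}")
    draw_frame = tails[patient]
    missing = [p for p in selected if p not in draw_frame.columns]
    if missing:
        raise KeyError(f"no conditioned samples for parameters {missing}")
    fixed = {p: float(draw_frame[p].median()) for p in selected}
    free = [p for p in model.parameter_names if p not in fixed]
    return PatientModel(
        patient_label=patient, model=model, fixed_params=fixed, free_params=free
    )
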