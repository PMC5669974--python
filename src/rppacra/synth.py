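"""Synthetic two-sample RPPA tables with planted divergence.

Emulates the structure of the real panel: positive baseline intensities on
the instrument's working range, multiplicative log-normal measurement
noise between the two samples, a designated subset of proteins with
planted fold changes, and multiple phosphosite endpoints for designated
proteins.  Intended for end-to-end testing of the divergence-selection and
calibration stages without the real fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .rppa import RppaEndpoint, RppaTable


@dataclass(frozen=True)
class SyntheticRppaSpec:
    """Generator settings.

    ``planted_up`` / ``planted_down`` map protein names to fold changes
    (> 1); a ``down`` fold f plants a ratio of 1/f.  ``multi_site`` maps
    protein names to the number of phosphosite endpoints emitted for them
    (default one endpoint per protein).  The defaults mirror the real
    panel: 51 endpoints on a ~1e3-7e4 a.u. baseline with sigma = 0.2
    log-normal noise.
    """

    n_endpoints: int = 51
    planted_up: Mapping[str, float] = field(default_factory=dict)
    planted_down: Mapping[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.2
    baseline_range: tuple[float, float] = (1e3, 7e4)
    multi_site: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for fold in (*self.planted_up.values(), *self.planted_down.values()):
            if not fold > 1:
                raise ValueError("planted folds must exceed 1")
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ValueError(f"planted sets overlap: {sorted(overlap)}")
        lo, hi = self.baseline_range
        if not 0 < lo < hi:
            raise ValueError("baseline_range must be a positive interval")
        n_planted = len(self.planted_up) + len(self.planted_down)
        if self.n_endpoints < n_planted:
            raise ValueError("n_endpoints smaller than the planted sets")
        for n in self.multi_site.values():
            if n < 1:
                raise ValueError("multi_site counts must be >= 1")


def _protein_names(spec: SyntheticRppaSpec) -> list[str]:
    planted = list(spec.planted_up) + list(spec.planted_down)
    n_null = spec.n_endpoints - len(planted)
    return planted + [f"NULL{i:04d}" for i in range(n_null)]


def generate_rppa_table(spec: SyntheticRppaSpec) -> RppaTable:
    """Generate a reproducible synthetic panel.

    Per endpoint: l-OS baseline ~ Uniform(baseline_range); s-OS equals the
    baseline times the planted fold (1 for null proteins) times
    ``exp(Normal(0, noise_sigma))``.  Proteins listed in ``multi_site``
    contribute that many phosphosite endpoints (all sharing the protein's
    planted fold, with independent noise), on top of the endpoint budget's
    protein count.
    """
    rng = np.random.default_rng(spec.seed)
    folds = {**spec.planted_up,
             **{p: 1.0 / f for p, f in spec.planted_down.items()}}
    endpoints: list[RppaEndpoint] = []
    lo, hi = spec.baseline_range
    for i, protein in enumerate(_protein_names(spec)):
        n_sites = spec.multi_site.get(protein, 1)
        fold = folds.get(protein, 1.0)
        for site in range(n_sites):
            base = rng.uniform(lo, hi)
            noise = np.exp(rng.normal(0.0, spec.noise_sigma))
            label = f"{protein} (S{site + 1})" if n_sites > 1 else protein
            endpoints.append(
                RppaEndpoint(
                    catalog_id=f"SYN-{i:04d}-{site}",
                    antibody=label,
                    company="synthetic",
                    dilution="1:1",
                    value_lOS=base,
                    value_sOS=base * fold * noise,
                )
            )
    return RppaTable(endpoints=endpoints)
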