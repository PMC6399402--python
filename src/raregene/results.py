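"""Result records shared by the testing and correction stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BurdenResult:
    """Logistic burden test output for one gene.

    ``or_`` is the aggregate odds ratio per minor allele of burden:
    > 1 risk, < 1 protective.
    """

    beta: float
    se: float
    or_: float
    ci95_lo: float
    ci95_hi: float
    p_raw: float
    n_markers: int
    nmaf_cases: int
    nmaf_controls: int
    method: str = "wald"  # wald | firth
    testable: bool = True


@dataclass
class SkatResult:
    """Variance-component (SKAT) test output for one gene."""

    q_stat: float
    p_raw: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_method: str = "moment-matching"
    testable: bool = True


@dataclass
class GeneAssociationResult:
    """Per-gene association record accumulated across pipeline stages."""

    gene_id: str
    burden: BurdenResult
    skat: SkatResult
    p_burden_gc: float = np.nan
    p_skat_gc: float = np.nan
    p_burden_emp: float = np.nan
    p_skat_emp: float = np.nan
    selected: bool = False

    @property
    def direction(self) -> str:
        return "risk" if self.burden.or_ > 1.0 else "protective"


def results_to_frame(results: list[GeneAssociationResult]) -> pd.DataFrame:
    """Flatten association results into the standard output table."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene_id,
                "NMUT": r.burden.n_markers,
                "nMAF.aff": r.burden.nmaf_cases,
                "nMAF.ctr": r.burden.nmaf_controls,
                "OR": r.burden.or_,
                "CI_95lo": r.burden.ci95_lo,
                "CI_95up": r.burden.ci95_hi,
                "P_burden_raw": r.burden.p_raw,
                "P_SKAT_raw": r.skat.p_raw,
                "P_burden_gc": r.p_burden_gc,
                "P_SKAT_gc": r.p_skat_gc,
                "P_burden_emp": r.p_burden_emp,
                "P_SKAT_emp": r.p_skat_emp,
                "direction": r.direction,
                "selected": r.selected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "NMUT",
            "nMAF.aff",
            "nMAF.ctr",
            "OR",
            "CI_95lo",
            "CI_95up",
            "P_burden_raw",
            "P_SKAT_raw",
            "P_burden_gc",
            "P_SKAT_gc",
            "P_burden_emp",
            "P_SKAT_emp",
            "direction",
            "selected",
        ],
    )
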