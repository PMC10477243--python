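"""Poison-exon bookkeeping: inclusion percentages, NMD arithmetic, qPCR.

A poison exon carries a premature termination codon, so the included
isoform is degraded by nonsense-mediated decay (NMD). At steady state,
inhibiting NMD (e.g. UPF1 knockdown) multiplies the observable transcript
pool by `fold`; the fraction degraded under normal conditions is then
1 - 1/fold. A 3-fold increase therefore implies about two thirds of
transcripts are NMD substrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IsoformQuant",
    "percent_inclusion",
    "nmd_degraded_fraction",
    "delta_delta_ct",
    "welch_t_test",
]


@dataclass(frozen=True)
class IsoformQuant:
    """Signal for the exon-included and exon-skipped isoforms.

    Signals may be read counts or band intensities; optional amplicon
    lengths allow molar correction of length-proportional signals.
    """

    included_signal: float
    skipped_signal: float
    included_length: float | None = None
    skipped_length: float | None = None

    def __post_init__(self) -> None:
        if self.included_signal < 0 or self.skipped_signal < 0:
            raise ValueError("signals must be non-negative")
        if self.included_signal == 0 and self.skipped_signal == 0:
            raise ValueError("percent inclusion undefined for all-zero signals")


def percent_inclusion(quant: IsoformQuant, molar_correction: bool = False) -> float:
    """Percent of transcripts including the exon: 100*incl/(incl+skip).

    With ``molar_correction`` each signal is divided by its amplicon length
    first (intensity-per-base to molar proxy).
    """
    incl = quant.included_signal
    skip = quant.skipped_signal
    if molar_correction:
        if quant.included_length is None or quant.skipped_length is None:
            raise ValueError("molar correction requires both amplicon lengths")
        incl = incl / quant.included_length
        skip = skip / quant.skipped_length
    return 100.0 * incl / (incl + skip)


def nmd_degraded_fraction(fold_change: float) -> float:
    """Percent of transcripts degraded by NMD from the fold increase upon
    NMD inhibition: (1 - 1/fold) * 100."""
    if fold_change < 1:
        raise ValueError(
            "fold change upon NMD inhibition must be >= 1 under the steady-state model"
        )
    return (1.0 - 1.0 / fold_change) * 100.0


def delta_delta_ct(
    ct: pd.DataFrame,
    treated: str,
    control: str,
    efficiency: float = 2.0,
) -> float:
    """Relative quantity by the delta-delta-Ct method.

    ``ct`` needs columns condition, ct_target, ct_ref; Cts are averaged
    over replicates within condition. Returns efficiency**(-ddCt) with
    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control.
    """
    required = {"condition", "ct_target", "ct_ref"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    values = ct[["ct_target", "ct_ref"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("Ct values must be finite and positive")
    deltas = {}
    for cond in (treated, control):
        sub = ct[ct["condition"] == cond]
        if sub.empty:
            raise ValueError(f"condition {cond!r} missing from Ct table")
        deltas[cond] = sub["ct_target"].mean() - sub["ct_ref"].mean()
    ddct = deltas[treated] - deltas[control]
    return float(efficiency ** (-ddct))


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Two-sided Welch's t test: (t, Welch-Satterthwaite df, p).

    Intended for log-transformed spliced:unspliced ratios where variances
    differ between conditions.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both samples have zero variance but different means")
    result = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (
        va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
    )
    return float(result.statistic), float(df), float(result.pvalue)
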