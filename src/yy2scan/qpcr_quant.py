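"""qPCR quantification arithmetic: relative expression, percent input,
fold enrichment over a reference locus, and primer-efficiency QC.

Amplification efficiency is assumed to be exactly 2 per cycle in the
relative-expression computation.  Replicates are aggregated as mean Ct
per (sample, target) cell before taking deltas; the standard error of
the mean is propagated linearly in Ct space and exponentiated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

Role = Literal["expression", "chip_ip", "chip_input", "chip_prei"]
ROLES = ("expression", "chip_ip", "chip_input", "chip_prei")

DEFAULT_REFERENCE_GENE = "Gapdh"
DEFAULT_REFERENCE_LOCUS = "Gapdh_promoter"


class MissingRecordError(KeyError):
    """A (sample, target, role) cell required by a computation is absent."""


class CtTable:
    """Replicate Ct values keyed by (sample, target, role).

    Backed by a long-form DataFrame with columns sample, target, role, ct
    (one row per replicate reaction).
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sample", "target", "role", "ct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        bad_roles = set(df["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"invalid roles: {sorted(bad_roles)}")
        ct = pd.to_numeric(df["ct"], errors="raise")
        if not ((ct > 0) & ct.notna() & (ct != float("inf"))).all():
            raise ValueError("Ct values must be finite and positive")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CtTable":
        return cls(pd.read_csv(path, dtype={"sample": str, "target": str, "role": str}))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def cell(self, sample: str, target: str, role: Role) -> tuple[float, float, int]:
        """Mean Ct, SEM and replicate count for one cell."""
        sel = self.df[
            (self.df["sample"] == sample)
            & (self.df["target"] == target)
            & (self.df["role"] == role)
        ]["ct"]
        if sel.empty:
            raise MissingRecordError(f"no Ct records for ({sample!r}, {target!r}, {role!r})")
        n = len(sel)
        sem = float(sel.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return float(sel.mean()), sem, n

    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def targets(self, role: Role | None = None) -> list[str]:
        df = self.df if role is None else self.df[self.df["role"] == role]
        return sorted(df["target"].unique())


@dataclass(frozen=True)
class ExpressionResult:
    target: str
    sample: str
    calibrator: str
    ddct: float
    fold: float
    sem_fold: float


def relative_expression_ddct(
    table: CtTable,
    target: str,
    reference_gene: str,
    sample: str,
    calibrator_sample: str,
) -> ExpressionResult:
    """Relative expression by the comparative-Ct method, base 2.

    dCt_s = Ct(target, s) - Ct(reference, s);
    ddCt = dCt(sample) - dCt(calibrator); fold = 2 ** -ddCt.
    Replicate SEMs combine in quadrature in Ct space; the fold SEM is
    fold * ln(2) * sem(ddCt).
    """
    ct_ts, sem_ts, _ = table.cell(sample, target, "expression")
    ct_rs, sem_rs, _ = table.cell(sample, reference_gene, "expression")
    ct_tc, sem_tc, _ = table.cell(calibrator_sample, target, "expression")
    ct_rc, sem_rc, _ = table.cell(calibrator_sample, reference_gene, "expression")
    ddct = (ct_ts - ct_rs) - (ct_tc - ct_rc)
    fold = 2.0 ** -ddct
    sem_ddct = math.sqrt(sem_ts**2 + sem_rs**2 + sem_tc**2 + sem_rc**2)
    return ExpressionResult(target, sample, calibrator_sample, ddct, fold, fold * math.log(2) * sem_ddct)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 1.0) -> float:
    """IP recovery as a percentage of input chromatin.

    The input Ct is first adjusted for its dilution:
    adjusted = ct_input - log2(1 / input_fraction), then
    %input = 100 * 2 ** (adjusted - ct_ip).
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


@dataclass(frozen=True)
class EnrichmentResult:
    locus: str
    pct_input_ip: float
    pct_input_prei: float
    fold_over_reference: float
    sem: float = 0.0


def fold_enrichment(
    result_locus: tuple[float, float],
    reference_locus: tuple[float, float],
    subtract_background: bool = True,
) -> float:
    """Fold enrichment of a locus over a reference, in %-input space.

    Each argument is a ``(pct_input_ip, pct_input_prei)`` pair.  With
    background subtraction the pre-immune signal is removed from both;
    a negative locus numerator clamps to 0.
    """
    ip_locus, prei_locus = result_locus
    ip_ref, prei_ref = reference_locus
    if subtract_background:
        num = max(ip_locus - prei_locus, 0.0)
        den = ip_ref - prei_ref
    else:
        num = ip_locus
        den = ip_ref
    if den <= 0:
        raise ValueError("non-positive reference signal: fold undefined")
    return num / den


@dataclass(frozen=True)
class EfficiencyResult:
    slope: float
    efficiency_pct: float
    passes: bool


def primer_efficiency(standard_curve_slope: float) -> EfficiencyResult:
    """Amplification efficiency from a standard-curve slope (dCt per log10 dilution).

    efficiency% = (10 ** (-1/slope) - 1) * 100; passes when 90 <= E <= 110.
    """
    if standard_curve_slope >= 0:
        raise ValueError("standard curve slope must be negative")
    eff = (10.0 ** (-1.0 / standard_curve_slope) - 1.0) * 100.0
    return EfficiencyResult(standard_curve_slope, eff, 90.0 <= eff <= 110.0)


def chip_enrichment(
    table: CtTable,
    locus: str,
    reference_locus: str = DEFAULT_REFERENCE_LOCUS,
    sample: str | None = None,
    input_fraction: float = 1.0,
    subtract_background: bool = True,
) -> EnrichmentResult:
    """Percent-input and fold-over-reference for one locus from a Ct table."""
    samples = [sample] if sample is not None else table.samples()
    if len(samples) != 1:
        raise ValueError("specify `sample` when the table holds several samples")
    s = samples[0]

    def pct(target: str, role: Role) -> float:
        ct, _sem, _ = table.cell(s, target, role)
        ct_in, _sem_in, _ = table.cell(s, target, "chip_input")
        return percent_input(ct, ct_in, input_fraction)

    ip = pct(locus, "chip_ip")
    prei = pct(locus, "chip_prei")
    ip_ref = pct(reference_locus, "chip_ip")
    prei_ref = pct(reference_locus, "chip_prei")
    fold = fold_enrichment((ip, prei), (ip_ref, prei_ref), subtract_background)
    return EnrichmentResult(locus, ip, prei, fold)
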