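"""Allelic association statistics from genotype count tables.

Case/control genotype counts (n_MM / n_Mm / n_mm) are converted to allele
counts, oriented to the minor allele, and compared with a two-sided Fisher
exact test. The two-sided p-value follows the point-probability convention:
the sum of hypergeometric probabilities, over all tables with the observed
margins, that do not exceed the probability of the observed table (with a
small relative tolerance guarding floating-point ties). This is the
convention used by the classic implementations in R and scipy and is the one
that reproduces published values computed with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
import logging
import math

import numpy as np
from scipy.special import gammaln

from .core import (
    GenotypeCounts,
    GenotypeCountTable,
    NoControlDataError,
    UndefinedFrequencyError,
    UndefinedTestError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Relative tolerance used when comparing point probabilities, so that
#: mirror tables whose probabilities are equal in exact arithmetic are not
#: excluded by floating-point rounding.
REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allelic 2x2 table: rows = cases/controls, columns = minor/major alleles."""

    a: int  # cases, minor
    b: int  # cases, major
    c: int  # controls, minor
    d: int  # controls, major

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any((not isinstance(x, (int, np.integer))) or x < 0 for x in cells):
            raise ValidationError(f"table entries must be non-negative ints: {cells}")
        if sum(cells) == 0:
            raise UndefinedTestError("all-zero 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class AssociationResult:
    variant_key: str
    table: ContingencyTable2x2
    p_two_sided: float
    case_maf: Fraction
    control_maf: Fraction
    cohorts_used: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Counting

def allele_counts(n_MM: int, n_Mm: int, n_mm: int) -> tuple[int, int]:
    """Minor-allele and total allele counts from a genotype count triplet."""
    counts = GenotypeCounts(int(n_MM), int(n_Mm), int(n_mm))
    minor = counts.n_Mm + 2 * counts.n_mm
    total = 2 * counts.total
    return minor, total


def maf(minor_alleles: int, total_alleles: int) -> Fraction:
    """Minor allele frequency as an exact fraction."""
    if total_alleles <= 0:
        raise UndefinedFrequencyError("total allele count is zero")
    if minor_alleles > total_alleles:
        raise ValidationError(
            f"minor allele count {minor_alleles} exceeds total {total_alleles}"
        )
    return Fraction(minor_alleles, total_alleles)


def merge_cohorts(counts: GenotypeCountTable, variant: str,
                  cohort_ids: list[str] | None = None) -> GenotypeCounts:
    """Element-wise sum of genotype counts over non-NA cohorts.

    NA cohorts are skipped with a log message; if every requested cohort is
    NA a :class:`NoControlDataError` is raised.
    """
    cohort_ids = cohort_ids if cohort_ids is not None else counts.cohorts
    merged: GenotypeCounts | None = None
    used: list[str] = []
    for cohort in cohort_ids:
        c = counts.get(variant, cohort)
        if c is None:
            logger.info("cohort %r is NA for %r; skipped", cohort, variant)
            continue
        merged = c if merged is None else merged + c
        used.append(cohort)
    if merged is None:
        raise NoControlDataError(f"all cohorts NA for variant {variant!r}")
    return merged


# ---------------------------------------------------------------------------
# Fisher exact test

_logfact = gammaln(np.arange(1024, dtype=float) + 1.0)


def _log_factorials(n_max: int) -> np.ndarray:
    global _logfact
    if n_max >= _logfact.size:
        _logfact = gammaln(np.arange(2 * n_max, dtype=float) + 1.0)
    return _logfact


def _log_pmf_support(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log hypergeometric pmf for tables with margins (r1,r2,c1)."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    n = r1 + r2
    lf = _log_factorials(n)
    logpmf = (
        lf[r1] - lf[k] - lf[r1 - k]
        + lf[r2] - lf[c1 - k] - lf[r2 - (c1 - k)]
        - (lf[n] - lf[c1] - lf[n - c1])
    )
    return k, logpmf


def fisher_exact_two_sided(t: ContingencyTable2x2, *,
                           alternative: str = "two-sided") -> float:
    """Fisher exact p-value for an allelic 2x2 table.

    ``alternative`` may be ``"two-sided"`` (default, point-probability
    convention), ``"greater"`` (enrichment of the minor allele in cases) or
    ``"less"``. Degenerate margins (an empty row or column) give p = 1.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    k, logpmf = _log_pmf_support(r1, r2, c1)
    obs = t.a - k[0]  # index of observed cell in the support
    if alternative == "greater":
        return float(min(1.0, np.exp(logpmf[obs:]).sum()))
    if alternative == "less":
        return float(min(1.0, np.exp(logpmf[: obs + 1]).sum()))
    if alternative != "two-sided":
        raise ValidationError(f"unknown alternative {alternative!r}")
    log_obs = logpmf[obs]
    include = logpmf <= log_obs + math.log1p(REL_TOL)
    if include.all():  # every table in the support counts, incl. degenerate margins
        return 1.0
    return float(min(1.0, np.exp(logpmf[include]).sum()))


# ---------------------------------------------------------------------------
# End-to-end association

def associate(case_counts: GenotypeCounts, control_counts: GenotypeCountTable,
              variant: str, cohort_ids: list[str] | None = None) -> AssociationResult:
    """Allelic Fisher exact association of one variant.

    Controls are pooled over all non-NA cohorts (optionally restricted to
    ``cohort_ids``); the table is oriented so the minor allele — decided from
    the pooled case+control counts — is in the first column.
    """
    merged = merge_cohorts(control_counts, variant, cohort_ids)
    used = tuple(
        c for c in (cohort_ids if cohort_ids is not None else control_counts.cohorts)
        if control_counts.get(variant, c) is not None
    )
    case_m, case_total = allele_counts(*case_counts.as_tuple())
    ctrl_m, ctrl_total = allele_counts(*merged.as_tuple())
    # Orient to the minor allele over the pooled sample.
    if 2 * (case_m + ctrl_m) > case_total + ctrl_total:
        case_m, ctrl_m = case_total - case_m, ctrl_total - ctrl_m
    table = ContingencyTable2x2(case_m, case_total - case_m,
                                ctrl_m, ctrl_total - ctrl_m)
    return AssociationResult(
        variant_key=variant,
        table=table,
        p_two_sided=fisher_exact_two_sided(table),
        case_maf=maf(case_m, case_total) if case_total else Fraction(0),
        control_maf=maf(ctrl_m, ctrl_total) if ctrl_total else Fraction(0),
        cohorts_used=used,
    )


def associate_all(case_table: GenotypeCountTable, control_table: GenotypeCountTable,
                  case_cohort: str | None = None,
                  cohort_ids: list[str] | None = None) -> list[AssociationResult]:
    """Run :func:`associate` for every variant present in the case table."""
    case_cohort = case_cohort or case_table.cohorts[0]
    results = []
    for variant in case_table.variants:
        cases = case_table.get(variant, case_cohort)
        if cases is None:
            logger.warning("no case counts for %r; skipped", variant)
            continue
        try:
            results.append(associate(cases, control_table, variant, cohort_ids))
        except NoControlDataError:
            logger.warning("no control counts for %r; skipped", variant)
    return results
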