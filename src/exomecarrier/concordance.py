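"""Concordance testing of carrier estimates.

Two comparisons arise in carrier-rate epidemiology:

* **cohort vs cohort** — are allele frequencies from two exome resources
  consistent?  Tested with the two-sample proportion z-test on pooled
  variance,

      Z = (p̂₁ − p̂₂) / sqrt( p̂ (1 − p̂) (1/n₁ + 1/n₂) ),

  with p̂ = (x₁ + x₂)/(n₁ + n₂) the pooled success fraction.  Without the
  continuity correction Z² is algebraically identical to the 2×2 Pearson
  chi-square statistic; with the correction |p̂₁ − p̂₂| is reduced by
  (1/n₁ + 1/n₂)/2 (floored at zero) before standardisation.

* **cohort vs literature prevalence** — is an observed AC/AN consistent with
  an externally reported allele frequency?  Tested with a one-sample
  goodness-of-fit chi-square on the expected allele counts (df = 1, no
  continuity correction).  Reference frequencies given as a range are
  evaluated at both endpoints, yielding a p-value interval.

No multiple-testing adjustment is applied by default; a Bonferroni option
exists for batch mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .counts import SiteObservation


@dataclass(frozen=True)
class ProportionTestResult:
    """Two-sample proportion test outcome."""

    p1_hat: float
    p2_hat: float
    n1: int
    n2: int
    pooled_p_hat: float
    z: float
    p_value: float
    continuity_corrected: bool
    degenerate: bool = False     # pooled estimate 0 or 1: no variance, p := 1


@dataclass(frozen=True)
class GofTestResult:
    """One-sample goodness-of-fit chi-square outcome."""

    observed_ac: int
    an: int
    expected_af: float
    chi2: float
    df: int
    p_value: float
    exact_agreement: bool = False  # expected_af == 0 and ac == 0
    unattainable: bool = False     # expected_af == 0 but ac > 0: infinite statistic


def two_proportion_test(
    ac1: int, an1: int, ac2: int, an2: int, continuity: bool = True
) -> ProportionTestResult:
    """Pooled-variance z-test of equality of two binomial proportions.

    Two-sided p-value from the standard normal.  When both cohorts have
    identical pooled outcome (pooled p̂ of 0 or 1) the statistic has no
    variance; the result is flagged degenerate with p = 1 rather than
    raising.
    """
    if an1 <= 0 or an2 <= 0:
        raise ValueError("allele denominators must be positive")
    if not (0 <= ac1 <= an1 and 0 <= ac2 <= an2):
        raise ValueError("need 0 <= ac <= an in both cohorts")
    p1 = ac1 / an1
    p2 = ac2 / an2
    pooled = (ac1 + ac2) / (an1 + an2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(
            p1_hat=p1, p2_hat=p2, n1=an1, n2=an2, pooled_p_hat=pooled,
            z=math.nan, p_value=1.0, continuity_corrected=continuity, degenerate=True,
        )
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / an1 + 1.0 / an2))
    diff = p1 - p2
    if continuity:
        correction = 0.5 * (1.0 / an1 + 1.0 / an2)
        adj = max(abs(diff) - correction, 0.0)
        z = math.copysign(adj, diff) / se
    else:
        z = diff / se
    p_value = 2.0 * stats.norm.sf(abs(z))
    return ProportionTestResult(
        p1_hat=p1, p2_hat=p2, n1=an1, n2=an2, pooled_p_hat=pooled,
        z=z, p_value=min(p_value, 1.0), continuity_corrected=continuity,
    )


def gof_test(ac: int, an: int, expected_af: float) -> GofTestResult:
    """Goodness-of-fit chi-square of observed AC/AN against an expected AF.

    chi² = (ac − e)²/e + ((an − ac) − (an − e))²/(an − e) with e = expected_af·an,
    df = 1, no continuity correction.  expected_af == 0 is handled specially:
    agreement (ac == 0) is flagged exact with p = 1; disagreement yields an
    infinite statistic flagged unattainable with p = 0.
    """
    if an <= 0:
        raise ValueError("an must be positive")
    if not 0 <= ac <= an:
        raise ValueError("need 0 <= ac <= an")
    if not 0.0 <= expected_af < 1.0:
        raise ValueError("expected_af must be in [0, 1)")
    if expected_af == 0.0:
        if ac == 0:
            return GofTestResult(ac, an, expected_af, chi2=0.0, df=1, p_value=1.0,
                                 exact_agreement=True)
        return GofTestResult(ac, an, expected_af, chi2=math.inf, df=1, p_value=0.0,
                             unattainable=True)
    e = expected_af * an
    chi2 = (ac - e) ** 2 / e + ((an - ac) - (an - e)) ** 2 / (an - e)
    p_value = float(stats.chi2.sf(chi2, df=1))
    return GofTestResult(ac, an, expected_af, chi2=chi2, df=1, p_value=p_value)


def gof_test_range(
    ac: int, an: int, expected_af_low: float, expected_af_high: float
) -> tuple[GofTestResult, GofTestResult]:
    """Evaluate the goodness-of-fit test at both endpoints of a reference range."""
    if expected_af_low > expected_af_high:
        raise ValueError("expected_af_low > expected_af_high")
    return gof_test(ac, an, expected_af_low), gof_test(ac, an, expected_af_high)


def batch_concordance(
    observations_a: Sequence[SiteObservation],
    observations_b: Sequence[SiteObservation],
    pairing: Optional[Sequence[tuple[str, str]]] = None,
    continuity: bool = True,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Pair-wise proportion tests between two cohorts' observations.

    Observations are keyed by mutation; ``pairing`` lists (population_a,
    population_b) group pairs to compare (e.g. an ancestry matched across
    cohorts).  When omitted, populations with identical codes are paired.
    Mutations present on only one side of a pair are emitted with status
    ``skipped`` rather than silently dropped; degenerate (0 vs 0)
    comparisons are labelled and never counted as significant.

    Returns a tidy frame with one row per (mutation × population pair) and
    the attributes ``n_significant`` / ``n_nonsignificant`` / ``n_degenerate``
    stored in ``DataFrame.attrs``.
    """
    index_a: dict[tuple[str, str], SiteObservation] = {
        (o.mutation_key, o.population): o for o in observations_a
    }
    index_b: dict[tuple[str, str], SiteObservation] = {
        (o.mutation_key, o.population): o for o in observations_b
    }
    if pairing is None:
        pops_a = {p for _, p in index_a}
        pops_b = {p for _, p in index_b}
        pairing = [(p, p) for p in sorted(pops_a & pops_b)]
    mutations = sorted({m for m, _ in index_a} | {m for m, _ in index_b})
    n_tests = sum(
        1
        for pa, pb in pairing
        for m in mutations
        if (m, pa) in index_a and (m, pb) in index_b
    )
    threshold = alpha / n_tests if (bonferroni and n_tests) else alpha

    rows = []
    for pop_a, pop_b in pairing:
        for m in mutations:
            oa = index_a.get((m, pop_a))
            ob = index_b.get((m, pop_b))
            if oa is None and ob is None:
                continue
            if oa is None or ob is None:
                rows.append(
                    {
                        "mutation_key": m, "population_a": pop_a, "population_b": pop_b,
                        "ac_a": oa.ac if oa else pd.NA, "an_a": oa.an if oa else pd.NA,
                        "ac_b": ob.ac if ob else pd.NA, "an_b": ob.an if ob else pd.NA,
                        "z": math.nan, "p_value": math.nan,
                        "status": "skipped", "significant": False,
                    }
                )
                continue
            res = two_proportion_test(oa.ac, oa.an, ob.ac, ob.an, continuity=continuity)
            status = "degenerate" if res.degenerate else "tested"
            significant = (not res.degenerate) and res.p_value < threshold
            rows.append(
                {
                    "mutation_key": m, "population_a": pop_a, "population_b": pop_b,
                    "ac_a": oa.ac, "an_a": oa.an, "ac_b": ob.ac, "an_b": ob.an,
                    "z": res.z, "p_value": res.p_value,
                    "status": status, "significant": significant,
                }
            )
    df = pd.DataFrame(rows)
    tested = df[df["status"] == "tested"] if len(df) else df
    df.attrs["alpha"] = threshold
    df.attrs["n_comparisons"] = int((df["status"] != "skipped").sum()) if len(df) else 0
    df.attrs["n_significant"] = int(tested["significant"].sum()) if len(tested) else 0
    df.attrs["n_nonsignificant"] = (
        int((~tested["significant"]).sum()) if len(tested) else 0
    )
    df.attrs["n_degenerate"] = int((df["status"] == "degenerate").sum()) if len(df) else 0
    return df
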