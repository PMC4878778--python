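"""Carrier-rate estimation under the rare-allele Hardy-Weinberg approximation.

For a recessive disorder with causal allele frequency p (wild-type q = 1-p),
random mating gives genotype frequencies p², 2pq, q².  Sampled cohorts are
depleted for affected homozygotes, but when the implied prevalence p² is
essentially zero (< 0.25%, i.e. p < 0.05) the carrier fraction is
approximated by

    p² + 2pq · ½ = p² + pq ≈ pq ≈ p,

so the operational "carrier rate" equals the causal allele frequency itself.
That convention is used throughout the reporting surface; the textbook
heterozygote frequency 2pq is computed alongside so callers can choose.
Rates are also expressed in the reciprocal "1 in N" form familiar from
screening tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .counts import SiteObservation
from .errors import UndefinedEstimateError

#: validity bound of the rare-allele approximation: p < 0.05 (prevalence p² < 0.25%)
HWE_AF_BOUND = 0.05


@dataclass(frozen=True)
class CarrierEstimate:
    """Carrier-rate estimate for one site observation."""

    observation: SiteObservation
    af: float
    carrier_rate: float      # == af under the rare-allele approximation
    het_frequency: float     # 2·p·(1−p), the textbook heterozygote frequency
    one_in: float            # 1/af; inf when ac == 0
    hwe_valid: bool          # af within the approximation's stated regime

    @property
    def mutation_key(self) -> str:
        return self.observation.mutation_key

    @property
    def population(self) -> str:
        return self.observation.population


def one_in(af: float) -> float:
    """Reciprocal "1 in N" form of a frequency; af == 0 gives math.inf."""
    if af < 0 or af > 1:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    if af == 0:
        return math.inf
    return 1.0 / af


def estimate_carrier(obs: SiteObservation) -> CarrierEstimate:
    """Convert an AC/AN observation into a carrier-rate estimate.

    The validity flag is False when af ≥ 0.05 — outside that regime the
    carrier rate ≈ allele frequency shortcut under-approximates 2pq and the
    homozygote depletion of the sampled cohort is no longer negligible.  The
    numeric outputs are produced regardless.
    """
    if obs.an <= 0:
        raise UndefinedEstimateError(f"{obs.mutation_key}: no called alleles (an == 0)")
    af = obs.ac / obs.an
    valid = af < HWE_AF_BOUND
    return CarrierEstimate(
        observation=obs,
        af=af,
        carrier_rate=af,
        het_frequency=2.0 * af * (1.0 - af),
        one_in=one_in(af),
        hwe_valid=valid,
    )


class RankedEstimate(NamedTuple):
    rank: int               # competition ranking; ties share a rank
    estimate: CarrierEstimate


def _display_af(af: float, sigfigs: int = 3) -> float:
    """Round to the display precision used for tie grouping (3 sig. figs)."""
    if af == 0:
        return 0.0
    return float(f"{af:.{sigfigs - 1}e}")


def rank_mutations(
    estimates: Sequence[CarrierEstimate],
    disease: Optional[str] = None,
    population: Optional[str] = None,
) -> list[RankedEstimate]:
    """Order carrier estimates by descending allele frequency.

    Estimates whose frequencies agree at display precision (3 significant
    figures) are grouped as ties and share a rank (competition ranking:
    1, 2, 2, 4, …).  Optional disease/population arguments filter the input
    first.  Permuting the input never changes the ranks; within a tie the
    original relative order is kept.
    """
    items = list(estimates)
    if disease is not None:
        items = [e for e in items if e.observation.record is not None
                 and e.observation.record.disease_name == disease]
    if population is not None:
        items = [e for e in items if e.population == population]
    items.sort(key=lambda e: -e.af)
    ranked: list[RankedEstimate] = []
    prev_disp: Optional[float] = None
    rank = 0
    for i, est in enumerate(items, start=1):
        disp = _display_af(est.af)
        if prev_disp is None or disp != prev_disp:
            rank = i
            prev_disp = disp
        ranked.append(RankedEstimate(rank=rank, estimate=est))
    return ranked


class DiseaseBurden(NamedTuple):
    disease: str
    population: str
    burden: float            # sum of per-mutation allele frequencies
    n_mutations: int
    approximate: bool        # always True: rare-allele independence approximation


def disease_burden(
    estimates: Sequence[CarrierEstimate],
    disease: str,
    population: str,
) -> DiseaseBurden:
    """Aggregate per-mutation carrier rates for one disease and population.

    Uses the sum of per-mutation allele frequencies — exact only in the
    limit of rare, independent alleles, hence flagged as an approximation.
    """
    members = [
        e
        for e in estimates
        if (e.observation.record is None or e.observation.record.disease_name == disease)
        and e.population == population
    ]
    return DiseaseBurden(
        disease=disease,
        population=population,
        burden=sum(e.af for e in members),
        n_mutations=len(members),
        approximate=True,
    )


def format_one_in(value: float) -> str:
    """Display form of a reciprocal rate, one decimal ("66.6", "inf" for 0 af)."""
    if math.isinf(value):
        return "inf"
    return f"{value:.1f}"
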