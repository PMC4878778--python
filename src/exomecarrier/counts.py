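"""Per-population allele counting from cohort VCFs.

The unit of evidence throughout the pipeline is the (AC, AN) pair: AC is the
number of alternate alleles observed for a panel mutation in a population,
AN the number of successfully called alleles at that site (2 per genotyped
diploid individual, minus missing alleles).  AN therefore varies site by
site with missingness, which is why carrier tables show varying
denominators for the same population.

Three entry points produce observations:

* :func:`count_alleles` — walk a VCF against a sample manifest and a
  mutation panel, applying site-level QC, and tally AC/AN per population;
* :func:`observations_from_table` — load printed AC/AN tables directly
  (e.g. published per-population count tables), bypassing VCF ingestion;
* :func:`pool_observations` — sum observations for one mutation across
  populations or cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ManifestError, ObservationError
from .panel import DiseasePanel, MutationRecord, _norm_chrom, _trim

log = logging.getLogger(__name__)

OBSERVATION_COLUMNS = ["mutation_key", "population", "cohort", "ac", "an"]


@dataclass(frozen=True)
class SiteObservation:
    """AC/AN for one mutation in one population of one cohort."""

    mutation_key: str
    population: str
    cohort: str
    ac: int
    an: int
    record: Optional[MutationRecord] = None

    def __post_init__(self) -> None:
        if self.an <= 0:
            raise ObservationError(
                f"{self.mutation_key}/{self.population}: an must be positive, got {self.an}"
            )
        if not 0 <= self.ac <= self.an:
            raise ObservationError(
                f"{self.mutation_key}/{self.population}: need 0 <= ac <= an, "
                f"got ac={self.ac}, an={self.an}"
            )

    @property
    def af(self) -> float:
        return self.ac / self.an


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    population: str
    superpopulation: str
    cohort: str
    sex: str = "unknown"


class SampleManifest:
    """sample → (population, superpopulation, cohort, sex) mapping.

    Enforces unique sample ids per cohort and a functional population →
    superpopulation mapping.
    """

    def __init__(self, samples: Iterable[SampleInfo]):
        self._by_id: dict[str, SampleInfo] = {}
        pop_super: dict[str, str] = {}
        for s in samples:
            key = s.sample_id
            if key in self._by_id and self._by_id[key].cohort == s.cohort:
                raise ManifestError(f"duplicate sample id {s.sample_id!r} in cohort {s.cohort!r}")
            prior = pop_super.get(s.population)
            if prior is not None and prior != s.superpopulation:
                raise ManifestError(
                    f"population {s.population!r} maps to both superpopulations "
                    f"{prior!r} and {s.superpopulation!r}"
                )
            pop_super[s.population] = s.superpopulation
            self._by_id[key] = s
        if not self._by_id:
            raise ManifestError("empty sample manifest")
        self.pop_super = pop_super

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> SampleInfo:
        return self._by_id[sample_id]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for s in self._by_id.values():
            if s.population not in seen:
                seen.append(s.population)
        return seen

    def population_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self._by_id.values():
            out[s.population] = out.get(s.population, 0) + 1
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"sample_id", "population", "superpopulation", "cohort"}
        missing = required - set(df.columns)
        if missing:
            raise ManifestError(f"{path}: manifest missing columns {sorted(missing)}")
        return cls(
            SampleInfo(
                sample_id=row.sample_id,
                population=row.population,
                superpopulation=row.superpopulation,
                cohort=row.cohort,
                sex=getattr(row, "sex", "unknown") or "unknown",
            )
            for row in df.itertuples()
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "sample_id": s.sample_id,
                "population": s.population,
                "superpopulation": s.superpopulation,
                "cohort": s.cohort,
                "sex": s.sex,
            }
            for s in self._by_id.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class QcConfig:
    """Site-level QC thresholds.

    The four filter dimensions are total read depth, fraction of samples
    with a called genotype, the alternate-read fraction in heterozygotes,
    and mean read position of alternate alleles.  Each filter applies only
    when the corresponding VCF field is present (DP, genotypes, AD, and the
    ``READPOS`` INFO field respectively); the read-position filter is
    disabled by default because site-level VCFs rarely carry it.
    """

    min_total_depth: int = 10
    min_fraction_samples_called: float = 0.8
    het_alt_fraction_range: tuple[float, float] = (0.25, 0.75)
    mean_read_position_range: Optional[tuple[float, float]] = None
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction_samples_called <= 1.0:
            raise ValueError("min_fraction_samples_called must be in [0, 1]")
        lo, hi = self.het_alt_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("het_alt_fraction_range must satisfy 0 <= low <= high <= 1")
        if self.mean_read_position_range is not None:
            lo, hi = self.mean_read_position_range
            if lo > hi:
                raise ValueError("mean_read_position_range low > high")

    @classmethod
    def disabled(cls) -> "QcConfig":
        return cls(enabled=False)


_AUTOSOMES = {str(c) for c in range(1, 23)}


def _check_autosomal(panel: DiseasePanel) -> None:
    for rec in panel:
        if rec.locus is not None and _norm_chrom(rec.locus.chrom) not in _AUTOSOMES:
            raise ObservationError(
                f"panel entry {rec.key} is non-autosomal (chrom {rec.locus.chrom}); "
                "allele counting assumes diploid autosomal genotypes"
            )


def _site_qc(variant, alt_index: int, n_samples: int, qc: QcConfig) -> Optional[str]:
    """Return a failure reason, or None if the site passes QC."""
    if not qc.enabled:
        return None
    dp = variant.INFO.get("DP")
    if dp is not None and dp < qc.min_total_depth:
        return f"total depth {dp} < {qc.min_total_depth}"
    called = sum(1 for g in variant.genotypes if g[0] != -1 or g[1] != -1)
    if n_samples and called / n_samples < qc.min_fraction_samples_called:
        return (
            f"called fraction {called / n_samples:.3f} < {qc.min_fraction_samples_called}"
        )
    try:
        ad = variant.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        alt_allele = alt_index + 1
        fracs = []
        for g, depths in zip(variant.genotypes, ad):
            alleles = [a for a in g[:2] if a != -1]
            if sorted(alleles) == sorted([0, alt_allele]):
                tot = int(depths[0]) + int(depths[alt_allele])
                if tot > 0:
                    fracs.append(int(depths[alt_allele]) / tot)
        if fracs:
            mean_frac = sum(fracs) / len(fracs)
            lo, hi = qc.het_alt_fraction_range
            if not lo <= mean_frac <= hi:
                return f"mean het alt fraction {mean_frac:.3f} outside [{lo}, {hi}]"
    if qc.mean_read_position_range is not None:
        rp = variant.INFO.get("READPOS")
        if rp is not None:
            lo, hi = qc.mean_read_position_range
            if not lo <= float(rp) <= hi:
                return f"mean read position {rp} outside [{lo}, {hi}]"
    return None


def count_alleles(
    vcf_path: str | Path,
    manifest: SampleManifest,
    panel: DiseasePanel,
    qc: Optional[QcConfig] = None,
    contig_aliases: Optional[Mapping[str, str]] = None,
) -> list[SiteObservation]:
    """Tally per-population AC/AN for panel mutations found in a VCF.

    Multi-allelic records are decomposed into biallelic (ref, alt) pairs
    before panel matching; AN at a decomposed site still counts every called
    allele.  Missing genotypes contribute nothing to AN; half-called
    genotypes contribute their single called allele.  Sites failing QC are
    excluded entirely, with the reason logged.

    Raises ManifestError if the VCF carries a sample absent from the manifest.
    """
    from cyvcf2 import VCF

    qc = qc if qc is not None else QcConfig()
    _check_autosomal(panel)
    vcf = VCF(str(vcf_path), gts012=False)
    samples: Sequence[str] = vcf.samples
    unknown = [s for s in samples if s not in manifest]
    if unknown:
        raise ManifestError(f"VCF samples not in manifest: {unknown[:5]}" + ("…" if len(unknown) > 5 else ""))
    sample_pop = [manifest[s].population for s in samples]
    sample_cohort = [manifest[s].cohort for s in samples]
    aliases = dict(contig_aliases or {})

    tallies: dict[tuple[str, str, str], list[int]] = {}
    for variant in vcf:
        chrom = aliases.get(variant.CHROM, variant.CHROM)
        for alt_index, alt in enumerate(variant.ALT):
            pos, ref, alt_norm = _trim(variant.POS, variant.REF, alt)
            rec = panel.match_variant(
                chrom=chrom, pos=pos, ref=ref, alt=alt_norm, rsid=variant.ID or None
            )
            if rec is None:
                continue
            reason = _site_qc(variant, alt_index, len(samples), qc)
            if reason is not None:
                log.info("QC fail %s %s:%s %s>%s: %s", rec.key, chrom, pos, ref, alt_norm, reason)
                continue
            alt_allele = alt_index + 1
            for g, pop, cohort in zip(variant.genotypes, sample_pop, sample_cohort):
                key = (rec.key, pop, cohort)
                if key not in tallies:
                    tallies[key] = [0, 0]
                for a in g[:2]:
                    if a == -1:
                        continue
                    tallies[key][1] += 1
                    if a == alt_allele:
                        tallies[key][0] += 1
    out = []
    for (mkey, pop, cohort), (ac, an) in sorted(tallies.items()):
        if an == 0:
            continue
        out.append(
            SiteObservation(
                mutation_key=mkey, population=pop, cohort=cohort, ac=ac, an=an,
                record=panel.by_key(mkey),
            )
        )
    return out


def pool_observations(
    observations: Sequence[SiteObservation],
    population: str = "POOLED",
    cohort: str = "POOLED",
) -> SiteObservation:
    """Sum AC and AN across observations of a single mutation.

    The pooled allele frequency is the count-weighted mean of the component
    frequencies, so it always lies within their range.
    """
    if not observations:
        raise ObservationError("cannot pool an empty observation collection")
    keys = {o.mutation_key for o in observations}
    if len(keys) != 1:
        raise ObservationError(f"pooling observations of mixed mutations: {sorted(keys)}")
    return SiteObservation(
        mutation_key=observations[0].mutation_key,
        population=population,
        cohort=cohort,
        ac=sum(o.ac for o in observations),
        an=sum(o.an for o in observations),
        record=observations[0].record,
    )


def observations_from_table(path: str | Path, panel: Optional[DiseasePanel] = None) -> list[SiteObservation]:
    """Load a printed AC/AN table (TSV: mutation_key, population, cohort, ac, an)."""
    df = pd.read_csv(path, sep="\t", dtype={"mutation_key": str, "population": str, "cohort": str})
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ObservationError(f"{path}: observation table missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            rec = panel.by_key(row.mutation_key) if panel is not None else None
        except KeyError:
            rec = None
        try:
            out.append(
                SiteObservation(
                    mutation_key=row.mutation_key,
                    population=row.population,
                    cohort=row.cohort,
                    ac=int(row.ac),
                    an=int(row.an),
                    record=rec,
                )
            )
        except (ObservationError, ValueError) as exc:
            raise ObservationError(f"{path} row {i}: {exc}") from exc
    return out


def observations_to_table(observations: Sequence[SiteObservation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "mutation_key": o.mutation_key,
                "population": o.population,
                "cohort": o.cohort,
                "ac": o.ac,
                "an": o.an,
            }
            for o in observations
        ]
    ).to_csv(path, sep="\t", index=False)
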