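"""Synthetic population cohorts with known truth.

Generates cohort VCFs (plus sample manifest and truth record) under the
same statistical model the analysis assumes: per individual and site, the
alternate-allele dosage is drawn Binomial(2, af) (Hardy-Weinberg random
mating); each true alternate allele is then independently dropped to
reference with probability sigma (the per-allele false-negative rate of
sequencing — the σ of the detection-power model); finally whole genotypes
go missing with probability missing_rate.  False-positive calls are outside
the model, matching the single-σ error semantics.

Seeding uses one master seed from which per-population substreams are
derived deterministically, so a fixed seed reproduces the cohort
byte-for-byte.

:func:`sample_allele_counts` exposes the same generative model marginally
(AC ~ thinned binomial) without materialising a VCF; simulation studies at
hundreds of replicates use it so the full file round-trip does not dominate
run time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .counts import SampleInfo, SampleManifest
from .errors import ObservationError
from .panel import DiseasePanel, Locus, MutationRecord


@dataclass(frozen=True)
class PopulationSpec:
    code: str
    superpopulation: str
    cohort: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"population {self.code}: n_individuals must be >= 1")


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    truth_af maps mutation key → population code → true allele frequency.
    """

    populations: list[PopulationSpec]
    truth_af: dict[str, dict[str, float]]
    sigma: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    emit_depth: bool = False
    mean_depth: int = 30

    def __post_init__(self) -> None:
        for rate, name in ((self.sigma, "sigma"), (self.missing_rate, "missing_rate")):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        for mkey, pops in self.truth_af.items():
            for pop, af in pops.items():
                if not 0.0 <= af <= 1.0:
                    raise ValueError(f"truth af for {mkey}/{pop} outside [0, 1]: {af}")


@dataclass
class CohortTruth:
    """Pre-error genotype matrices and the spec that generated them."""

    spec: CohortSpec
    sample_ids: list[str]
    #: mutation key → array of true alt dosages (0/1/2), one per sample
    true_dosage: dict[str, np.ndarray]

    def true_ac_an(self, mutation_key: str, population: Optional[str] = None,
                   manifest: Optional[SampleManifest] = None) -> tuple[int, int]:
        dos = self.true_dosage[mutation_key]
        if population is None:
            return int(dos.sum()), 2 * len(dos)
        assert manifest is not None
        mask = np.array([manifest[s].population == population for s in self.sample_ids])
        return int(dos[mask].sum()), 2 * int(mask.sum())

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.spec.seed,
            "sigma": self.spec.sigma,
            "missing_rate": self.spec.missing_rate,
            "truth_af": self.spec.truth_af,
            "sample_ids": self.sample_ids,
            "true_dosage": {k: v.tolist() for k, v in self.true_dosage.items()},
        }
        Path(path).write_text(json.dumps(doc))


def make_synthetic_panel(n_sites: int, chrom: str = "1", spacing: int = 1000) -> DiseasePanel:
    """A panel of n_sites synthetic SNVs (one disease per site) for simulations."""
    entries = [
        MutationRecord(
            disease_name=f"synthetic disorder {i}",
            gene_symbol=f"SYNG{i}",
            hgvs_c=f"c.{i + 1}A>G",
            rsid=f"rsSYN{i}",
            locus=Locus(chrom=chrom, pos=(i + 1) * spacing, ref="A", alt="G"),
        )
        for i in range(n_sites)
    ]
    return DiseasePanel(entries=entries, name="synthetic", version="sim")


def _population_rngs(spec: CohortSpec) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(spec.populations))
    return {p.code: np.random.default_rng(c) for p, c in zip(spec.populations, children)}


def generate_cohort(
    spec: CohortSpec,
    panel: DiseasePanel,
    out_dir: str | Path,
    prefix: str = "cohort",
) -> tuple[Path, Path, CohortTruth]:
    """Write a synthetic cohort VCF + manifest; return paths and truth record.

    Every panel mutation with a locus gets one VCF record; truth_af keys must
    exist in the panel.  Populations absent from a mutation's truth_af entry
    default to allele frequency 0.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel_keys = {rec.key for rec in panel}
    for mkey in spec.truth_af:
        if mkey not in panel_keys:
            raise ObservationError(f"truth_af references unknown mutation {mkey!r}")

    sites = [rec for rec in panel if rec.locus is not None]
    samples: list[SampleInfo] = []
    for p in spec.populations:
        for i in range(p.n_individuals):
            samples.append(
                SampleInfo(
                    sample_id=f"{p.code}{i:04d}",
                    population=p.code,
                    superpopulation=p.superpopulation,
                    cohort=p.cohort,
                )
            )
    sample_ids = [s.sample_id for s in samples]
    n_total = len(samples)

    rngs = _population_rngs(spec)
    # per-population index ranges in sample order
    ranges: dict[str, tuple[int, int]] = {}
    start = 0
    for p in spec.populations:
        ranges[p.code] = (start, start + p.n_individuals)
        start += p.n_individuals

    true_dosage: dict[str, np.ndarray] = {}
    obs_dosage: dict[str, np.ndarray] = {}   # -1 encodes missing genotype
    for rec in sites:
        true = np.zeros(n_total, dtype=np.int64)
        obs = np.zeros(n_total, dtype=np.int64)
        for p in spec.populations:
            rng = rngs[p.code]
            af = spec.truth_af.get(rec.key, {}).get(p.code, 0.0)
            lo, hi = ranges[p.code]
            t = rng.binomial(2, af, size=hi - lo)
            # each true alt allele independently missed with prob sigma
            kept = t - rng.binomial(t, spec.sigma) if spec.sigma > 0 else t
            miss = rng.random(hi - lo) < spec.missing_rate
            o = kept.copy()
            o[miss] = -1
            true[lo:hi] = t
            obs[lo:hi] = o
        true_dosage[rec.key] = true
        obs_dosage[rec.key] = obs

    vcf_path = out_dir / f"{prefix}.vcf"
    manifest_path = out_dir / f"{prefix}.manifest.tsv"
    truth_path = out_dir / f"{prefix}.truth.json"
    _write_vcf(vcf_path, sites, sample_ids, obs_dosage, spec, rngs)
    manifest = SampleManifest(samples)
    manifest.to_tsv(manifest_path)
    truth = CohortTruth(spec=spec, sample_ids=sample_ids, true_dosage=true_dosage)
    truth.to_json(truth_path)
    return vcf_path, manifest_path, truth


def _write_vcf(
    path: Path,
    sites: Sequence[MutationRecord],
    sample_ids: Sequence[str],
    obs_dosage: Mapping[str, np.ndarray],
    spec: CohortSpec,
    rngs: Mapping[str, np.random.Generator],
) -> None:
    contigs: list[str] = []
    for rec in sites:
        if rec.locus.chrom not in contigs:
            contigs.append(rec.locus.chrom)
    lines = ["##fileformat=VCFv4.2", "##source=exomecarrier-synthetic"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if spec.emit_depth:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">')
        lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    # depth draws come from a dedicated substream so GT streams stay untouched
    depth_rng = np.random.default_rng(np.random.SeedSequence(spec.seed + 2**20))
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    ordered = sorted(sites, key=lambda r: (r.locus.chrom, r.locus.pos))
    for rec in ordered:
        obs = obs_dosage[rec.key]
        if spec.emit_depth:
            dps = depth_rng.poisson(spec.mean_depth, size=len(obs)).astype(int)
            cells = []
            for dos, dp in zip(obs, dps):
                gt = gt_of[int(dos)]
                if dos == -1:
                    cells.append(f"{gt}:0:0,0")
                    continue
                alt_reads = int(round(dp * dos / 2))
                cells.append(f"{gt}:{dp}:{dp - alt_reads},{alt_reads}")
            info = f"DP={int(dps.sum())}"
            fmt = "GT:DP:AD"
        else:
            cells = [gt_of[int(d)] for d in obs]
            info = f"DP={spec.mean_depth * len(obs)}"
            fmt = "GT"
        lines.append(
            "\t".join(
                [
                    rec.locus.chrom, str(rec.locus.pos), rec.rsid or ".",
                    rec.locus.ref, rec.locus.alt, ".", "PASS", info, fmt,
                ]
                + cells
            )
        )
    path.write_text("\n".join(lines) + "\n")


def sample_allele_counts(
    af: float,
    n_individuals: int,
    sigma: float = 0.0,
    missing_rate: float = 0.0,
    size: int = 1,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (ac, an) draws under the cohort generative model.

    Marginally identical to counting alleles on a generated VCF: per
    replicate, true AC ~ Binomial(2·n_called, af) with each alt allele kept
    with probability (1−σ); n_called ~ Binomial(n_individuals, 1−missing).
    Returns arrays of shape (size,).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    called = rng.binomial(n_individuals, 1.0 - missing_rate, size=size)
    an = 2 * called
    true_ac = rng.binomial(an, af)
    ac = true_ac - rng.binomial(true_ac, sigma) if sigma > 0 else true_ac
    return ac, an


# re-exported printed-count fixtures (the in-study acceptance data)
from .fixtures import make_exac_fixture, make_panel, make_table1_fixture  # noqa: E402,F401
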