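"""Allele counting: VCF tallies, QC filtering, pooling, printed-table ingestion."""

import numpy as np
import pytest

from exomecarrier import (
    QcConfig,
    SampleManifest,
    SiteObservation,
    count_alleles,
    generate_cohort,
    make_synthetic_panel,
    observations_from_table,
    pool_observations,
)
from exomecarrier.counts import SampleInfo, observations_to_table
from exomecarrier.errors import ManifestError, ObservationError
from exomecarrier.panel import DiseasePanel, Locus, MutationRecord
from exomecarrier.simulate import CohortSpec, PopulationSpec


def write_vcf(path, records, samples):
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path.write_text("\n".join(header + records) + "\n")
    return path


@pytest.fixture
def tiny_panel():
    return DiseasePanel(
        entries=[
            MutationRecord(disease_name="d1", gene_symbol="G1", hgvs_c="c.1A>G",
                           rsid="rs100", locus=Locus("1", 1000, "A", "G")),
            MutationRecord(disease_name="d2", gene_symbol="G2", hgvs_c="c.2C>T",
                           rsid="rs200", locus=Locus("1", 2000, "C", "T")),
        ]
    )


@pytest.fixture
def tiny_manifest():
    return SampleManifest(
        SampleInfo(f"S{i}", "POP1", "SUP1", "test") for i in range(5)
    )


class TestCountAlleles:
    def test_hand_tally_with_missing_genotype(self, tmp_path, tiny_panel, tiny_manifest):
        # genotypes {0/1, 0/0, 1/1, 0/1, ./.} -> ac=4, an=8
        vcf = write_vcf(
            tmp_path / "t.vcf",
            ["1\t1000\trs100\tA\tG\t.\tPASS\tDP=100\tGT\t0/1\t0/0\t1/1\t0/1\t./."],
            [f"S{i}" for i in range(5)],
        )
        (obs,) = count_alleles(vcf, tiny_manifest, tiny_panel)
        assert (obs.ac, obs.an) == (4, 8)
        assert obs.mutation_key == "G1:c.1A>G"

    def test_half_called_genotype_contributes_one_allele(self, tmp_path, tiny_panel, tiny_manifest):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            ["1\t1000\trs100\tA\tG\t.\tPASS\tDP=100\tGT\t1/.\t0/0\t0/0\t0/0\t0/0"],
            [f"S{i}" for i in range(5)],
        )
        (obs,) = count_alleles(vcf, tiny_manifest, tiny_panel, qc=QcConfig.disabled())
        assert (obs.ac, obs.an) == (1, 9)

    def test_all_reference_site_gives_zero_ac(self, tmp_path, tiny_panel, tiny_manifest):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            ["1\t1000\trs100\tA\tG\t.\tPASS\tDP=100\tGT\t" + "\t".join(["0/0"] * 5)],
            [f"S{i}" for i in range(5)],
        )
        (obs,) = count_alleles(vcf, tiny_manifest, tiny_panel)
        assert (obs.ac, obs.an) == (0, 10)

    def test_multiallelic_decomposition(self, tmp_path, tiny_manifest):
        # panel targets the 2nd alt; AN counts every called allele at the site
        panel = DiseasePanel(entries=[
            MutationRecord(disease_name="d", gene_symbol="G", hgvs_c="c.1A>C",
                           rsid="rs1", locus=Locus("1", 1000, "A", "C")),
        ])
        vcf = write_vcf(
            tmp_path / "t.vcf",
            ["1\t1000\trs1\tA\tG,C\t.\tPASS\tDP=100\tGT\t1/2\t0/2\t0/0\t0/1\t2/2"],
            [f"S{i}" for i in range(5)],
        )
        (obs,) = count_alleles(vcf, tiny_manifest, panel)
        assert (obs.ac, obs.an) == (4, 10)

    def test_unknown_vcf_sample_is_hard_error(self, tmp_path, tiny_panel, tiny_manifest):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            ["1\t1000\trs100\tA\tG\t.\tPASS\tDP=100\tGT\t0/0"],
            ["STRANGER"],
        )
        with pytest.raises(ManifestError, match="STRANGER"):
            count_alleles(vcf, tiny_manifest, tiny_panel)

    def test_contig_alias_resolves_chr_prefix(self, tmp_path, tiny_panel, tiny_manifest):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            ["1\t1000\trs100\tA\tG\t.\tPASS\tDP=100\tGT\t0/1\t0/0\t0/0\t0/0\t0/0"],
            [f"S{i}" for i in range(5)],
        )
        # alias maps the VCF dialect onto panel naming
        (obs,) = count_alleles(vcf, tiny_manifest, tiny_panel, contig_aliases={"1": "chr1"})
        assert obs.ac == 1  # chr-insensitive matching still finds the record

    def test_non_autosomal_panel_rejected(self, tmp_path, tiny_manifest):
        panel = DiseasePanel(entries=[
            MutationRecord(disease_name="d", gene_symbol="G", hgvs_c="c.1A>G",
                           rsid="rs1", locus=Locus("X", 1000, "A", "G")),
        ])
        vcf = write_vcf(tmp_path / "t.vcf", [], [f"S{i}" for i in range(5)])
        with pytest.raises(ObservationError, match="non-autosomal"):
            count_alleles(vcf, tiny_manifest, panel)

    def test_low_depth_site_filtered(self, tmp_path, tiny_panel, tiny_manifest):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            [
                "1\t1000\trs100\tA\tG\t.\tPASS\tDP=3\tGT\t0/1\t0/0\t0/0\t0/0\t0/0",
                "1\t2000\trs200\tC\tT\t.\tPASS\tDP=100\tGT\t0/1\t0/0\t0/0\t0/0\t0/0",
            ],
            [f"S{i}" for i in range(5)],
        )
        obs = count_alleles(vcf, tiny_manifest, tiny_panel, qc=QcConfig(min_total_depth=10))
        assert [o.mutation_key for o in obs] == ["G2:c.2C>T"]

    def test_low_call_rate_site_filtered(self, tmp_path, tiny_panel, tiny_manifest):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            ["1\t1000\trs100\tA\tG\t.\tPASS\tDP=100\tGT\t0/1\t./.\t./.\t./.\t0/0"],
            [f"S{i}" for i in range(5)],
        )
        assert count_alleles(vcf, tiny_manifest, tiny_panel) == []
        kept = count_alleles(
            vcf, tiny_manifest, tiny_panel, qc=QcConfig(min_fraction_samples_called=0.3)
        )
        assert [(o.ac, o.an) for o in kept] == [(1, 4)]

    def test_het_alt_fraction_filter_uses_ad(self, tmp_path, tiny_panel, tiny_manifest):
        rec = ("1\t1000\trs100\tA\tG\t.\tPASS\tDP=100\tGT:AD\t"
               "0/1:28,2\t0/1:29,1\t0/0:30,0\t0/0:30,0\t0/0:30,0")
        vcf = (tmp_path / "t.vcf")
        header = [
            "##fileformat=VCFv4.2", "##contig=<ID=1>",
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"S{i}" for i in range(5)),
        ]
        vcf.write_text("\n".join(header + [rec]) + "\n")
        # mean het alt fraction ~0.05: fails the allele-balance band
        assert count_alleles(vcf, tiny_manifest, tiny_panel) == []
        ok = count_alleles(vcf, tiny_manifest, tiny_panel, qc=QcConfig.disabled())
        assert [(o.ac, o.an) for o in ok] == [(2, 10)]

    def test_record_and_sample_order_invariance(self, tmp_path, tiny_panel, tiny_manifest):
        recs = [
            "1\t1000\trs100\tA\tG\t.\tPASS\tDP=100\tGT\t0/1\t1/1\t0/0\t0/1\t0/0",
            "1\t2000\trs200\tC\tT\t.\tPASS\tDP=100\tGT\t0/0\t0/1\t0/0\t0/0\t1/1",
        ]
        samples = [f"S{i}" for i in range(5)]
        v1 = write_vcf(tmp_path / "a.vcf", recs, samples)
        v2 = write_vcf(tmp_path / "b.vcf", recs[::-1], samples)
        o1 = count_alleles(v1, tiny_manifest, tiny_panel)
        o2 = count_alleles(v2, tiny_manifest, tiny_panel)
        assert [(o.mutation_key, o.ac, o.an) for o in o1] == [
            (o.mutation_key, o.ac, o.an) for o in o2
        ]

    def test_matches_brute_force_on_synthetic_cohort(self, tmp_path):
        """Pipeline tally equals direct summation over the truth genotype matrix."""
        panel = make_synthetic_panel(6)
        spec = CohortSpec(
            populations=[
                PopulationSpec("POPA", "SUPA", "sim", 40),
                PopulationSpec("POPB", "SUPB", "sim", 25),
            ],
            truth_af={r.key: {"POPA": 0.3, "POPB": 0.1} for r in panel},
            sigma=0.0,
            missing_rate=0.1,
            seed=7,
        )
        vcf_path, manifest_path, truth = generate_cohort(spec, panel, tmp_path)
        manifest = SampleManifest.from_tsv(manifest_path)
        obs = count_alleles(vcf_path, manifest, panel, qc=QcConfig.disabled())
        # brute-force oracle over the emitted genotypes: parse the VCF text
        import re

        lines = [l for l in vcf_path.read_text().splitlines() if not l.startswith("#")]
        sample_ids = vcf_path.read_text().splitlines()
        header = next(l for l in sample_ids if l.startswith("#CHROM")).split("\t")[9:]
        pops = {s: manifest[s].population for s in header}
        expected = {}
        for line in lines:
            f = line.split("\t")
            key = panel.match_variant(chrom=f[0], pos=int(f[1]), ref=f[3], alt=f[4]).key
            for sid, gt in zip(header, f[9:]):
                alleles = re.split(r"[/|]", gt.split(":")[0])
                k = (key, pops[sid])
                ac_an = expected.setdefault(k, [0, 0])
                for a in alleles:
                    if a == ".":
                        continue
                    ac_an[1] += 1
                    ac_an[0] += int(a)
        got = {(o.mutation_key, o.population): [o.ac, o.an] for o in obs}
        assert got == expected


class TestPooling:
    def test_sca_african_pool(self, table1_cell):
        nhlbi = table1_cell("HBB:c.20A>T", "AA", "NHLBI")
        kg = table1_cell("HBB:c.20A>T", "AFR", "1000G")
        pooled = pool_observations([nhlbi, kg], population="African")
        assert (pooled.ac, pooled.an) == (222, 4894)
        assert pooled.af == pytest.approx(0.0454, abs=5e-5)

    def test_sca_european_pool(self, table1_cell):
        pooled = pool_observations(
            [table1_cell("HBB:c.20A>T", "EA", "NHLBI"),
             table1_cell("HBB:c.20A>T", "EUR", "1000G")],
            population="European",
        )
        assert (pooled.ac, pooled.an) == (2, 9354)
        assert pooled.af == pytest.approx(0.000214, abs=1e-6)

    def test_single_observation_identity(self, table1_cell):
        o = table1_cell("HBB:c.20A>T", "AMR", "1000G")
        pooled = pool_observations([o])
        assert (pooled.ac, pooled.an) == (o.ac, o.an)

    def test_mixed_mutations_rejected(self, table1_cell):
        with pytest.raises(ObservationError, match="mixed"):
            pool_observations([
                table1_cell("HBB:c.20A>T", "AA", "NHLBI"),
                table1_cell("CLEC7A:c.714T>G", "AA", "NHLBI"),
            ])

    def test_pooled_af_within_component_bounds(self, table1):
        rng = np.random.default_rng(0)
        for _ in range(50):
            picks = rng.choice(len(table1), size=rng.integers(2, 6), replace=False)
            group = [table1[i] for i in picks]
            key = group[0].mutation_key
            group = [o for o in table1 if o.mutation_key == key][:4]
            pooled = pool_observations(group)
            afs = [o.af for o in group]
            assert min(afs) - 1e-12 <= pooled.af <= max(afs) + 1e-12
            assert pooled.ac == sum(o.ac for o in group)
            assert pooled.an == sum(o.an for o in group)


class TestObservationTables:
    def test_roundtrip(self, table1, tmp_path):
        p = tmp_path / "obs.tsv"
        observations_to_table(table1, p)
        again = observations_from_table(p)
        assert [(o.mutation_key, o.population, o.cohort, o.ac, o.an) for o in again] == [
            (o.mutation_key, o.population, o.cohort, o.ac, o.an) for o in table1
        ]

    def test_printed_cells_load(self, table1_cell):
        sca = table1_cell("HBB:c.20A>T", "ALL", "POOLED")
        assert (sca.ac, sca.an) == (228, 15182)

    def test_exac_fixture_row(self):
        from exomecarrier import make_exac_fixture

        obs = make_exac_fixture()
        clec = next(o for o in obs if o.mutation_key == "CLEC7A:c.714T>G"
                    and o.population == "African")
        assert (clec.ac, clec.an) == (253, 10404)
        assert clec.af == pytest.approx(0.0243, abs=5e-5)

    def test_ac_exceeding_an_rejected_with_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("mutation_key\tpopulation\tcohort\tac\tan\nX:c.1A>T\tP\tC\t5\t4\n")
        with pytest.raises(ObservationError, match="row 2"):
            observations_from_table(p)

    def test_invariant_violation_direct(self):
        with pytest.raises(ObservationError):
            SiteObservation(mutation_key="X", population="P", cohort="C", ac=3, an=2)
        with pytest.raises(ObservationError):
            SiteObservation(mutation_key="X", population="P", cohort="C", ac=0, an=0)
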