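"""Printed-count fixtures: the published carrier table, panel, and reference AFs.

These are the AC/AN counts as printed in the source carrier-rate study of
18 recessive disorders screened against two population exome resources
(a 1,092-individual multi-ethnic cohort, "1000G", and a 6,503-individual
two-ethnicity cohort, "NHLBI"); 24 of the 161 panel mutations were detected
and their per-population counts published.  Shipping the printed counts
lets every downstream statistic (carrier rates, pooling, concordance tests)
be recomputed without any cohort download.

Row layout per mutation: 23 AC/AN cells in the fixed population order
``_ROW_ORDER`` — the pooled ALL row, the NHLBI rows (ALL/EA/AA), the 1000G
rows (ALL + 4 superpopulations + 14 populations).

Notes on individual cells:

* the NHLBI-ALL cell of ADAR:c.577C>A is printed as a bare frequency
  (0.00315); its counts are reconstructed as 41/13006 from row additivity
  (pooled ALL minus 1000G), which reproduces the printed frequency;
* two cells carry printed-frequency typos (AMR PLK1S1 "0.00588 (1/362)",
  AA RAB23 "0.00454 (2/4404)"); only the counts are stored and frequencies
  are always recomputed, so the typos do not propagate;
* SERAC1:c.1627_1628insTC has no dbSNP id in the source; the panel requires
  a locus in that case, so the fixture carries a synthetic placeholder
  locus (chr6) — adequate for matching round-trips, not a real coordinate.
"""

from __future__ import annotations

from .counts import SiteObservation
from .panel import DiseasePanel, Locus, MutationRecord

_ROW_ORDER: list[tuple[str, str]] = [
    ("ALL", "POOLED"),
    ("ALL", "NHLBI"),
    ("EA", "NHLBI"),
    ("AA", "NHLBI"),
    ("ALL", "1000G"),
    ("AFR", "1000G"),
    ("AMR", "1000G"),
    ("ASN", "1000G"),
    ("EUR", "1000G"),
    ("ASW", "1000G"),
    ("CEU", "1000G"),
    ("CHB", "1000G"),
    ("CHS", "1000G"),
    ("CLM", "1000G"),
    ("FIN", "1000G"),
    ("GBR", "1000G"),
    ("IBS", "1000G"),
    ("JPT", "1000G"),
    ("LWK", "1000G"),
    ("MXL", "1000G"),
    ("PUR", "1000G"),
    ("TSI", "1000G"),
    ("YRI", "1000G"),
]

#: 1000G population → superpopulation
POP_SUPER: dict[str, str] = {
    "ASW": "AFR", "LWK": "AFR", "YRI": "AFR",
    "CEU": "EUR", "FIN": "EUR", "GBR": "EUR", "IBS": "EUR", "TSI": "EUR",
    "CHB": "ASN", "CHS": "ASN", "JPT": "ASN",
    "CLM": "AMR", "MXL": "AMR", "PUR": "AMR",
    "EA": "EA", "AA": "AA",
}

# all-zero tail for the 18 rows after (ALL, NHLBI ALL/EA/AA, 1000G ALL)
_Z = ("0/492 0/362 0/572 0/758 0/122 0/170 0/194 0/200 0/120 0/186 0/178 "
      "0/28 0/178 0/194 0/132 0/110 0/196 0/176")

_CARRIER_TABLE: dict[str, str] = {
    "HBB:c.20A>T":
        "228/15182 179/12998 2/8596 177/4402 49/2184 45/492 4/362 0/572 0/758 "
        "3/122 0/170 0/194 0/200 1/120 0/186 0/178 0/28 0/178 19/194 0/132 "
        "3/110 0/196 23/176",
    "CLEC7A:c.714T>G":
        "869/15190 795/13006 679/8600 116/4406 74/2184 7/492 16/362 0/572 51/758 "
        "4/122 14/170 0/194 0/200 5/120 10/186 14/178 1/28 0/178 3/194 8/132 "
        "3/110 12/196 0/176",
    "PROP1:c.301_302delAG":
        "9/14702 9/12518 9/8254 0/4264 0/2184 " + _Z,
    "ASPA:c.854A>C":
        "3/15190 3/13006 2/8600 1/4406 0/2184 " + _Z,
    "ASPA:c.914C>A":
        "2/15190 2/13006 2/8600 0/4406 0/2184 " + _Z,
    "AP1S3:c.11T>G":
        "126/14180 115/11996 105/8232 10/3764 11/2184 2/492 1/362 0/572 8/758 "
        "2/122 2/170 0/194 0/200 0/120 1/186 1/178 2/28 0/178 0/194 0/132 "
        "1/110 2/196 0/176",
    "AP1S3:c.64A>G":
        "16/14098 13/11914 11/8188 2/3726 3/2184 0/492 1/362 0/572 2/758 "
        "0/122 0/170 0/194 0/200 0/120 0/186 0/178 0/28 0/178 0/194 0/132 "
        "1/110 2/196 0/176",
    "AP1S3:c.95C>T":
        "65/14166 58/11982 57/8280 1/3702 7/2184 0/492 2/362 0/572 5/758 "
        "0/122 2/170 0/194 0/200 2/120 0/186 2/178 0/28 0/178 0/194 0/132 "
        "0/110 1/196 0/176",
    "AP1S3:c.97C>T":
        "109/14054 102/11870 95/8174 7/3696 7/2184 0/492 1/362 0/572 6/758 "
        "0/122 1/170 0/194 0/200 0/120 1/186 3/178 1/28 0/178 0/194 0/132 "
        "1/110 0/196 0/176",
    "PLK1S1:c.226C>T":
        "5/14024 5/11840 5/8180 0/3660 0/2184 " + _Z,
    "MCPH1:c.74C>G":
        "1/14160 1/11976 1/8222 0/3754 0/2184 " + _Z,
    "CEP152:c.2000A>G":
        "56/14226 50/12042 1/8230 49/3812 6/2184 6/492 0/362 0/572 0/758 "
        "0/122 0/170 0/194 0/200 0/120 0/186 0/178 0/28 0/178 0/194 0/132 "
        "0/110 0/196 6/176",
    "CEP152:c.2034T>G":
        "10/14526 9/12342 2/8366 7/3976 1/2184 1/492 0/362 0/572 0/758 "
        "0/122 0/170 0/194 0/200 0/120 0/186 0/178 0/28 0/178 1/194 0/132 "
        "0/110 0/196 0/176",
    "EXOSC3:c.238G>T":
        "1/15154 1/12970 1/8586 0/4384 0/2184 " + _Z,
    "EXOSC3:c.395A>C":
        "11/15190 11/13006 11/8600 0/4406 0/2184 " + _Z,
    "DHODH:c.475-1269A>G":
        "1/15190 1/13006 1/8600 0/4406 0/2184 " + _Z,
    "DHODH:c.403C>T":
        "5/14206 5/12022 5/8232 0/3790 0/2184 " + _Z,
    "DHODH:c.454G>A":
        "1/14364 1/12180 1/8302 0/3878 0/2184 " + _Z,
    "DHODH:c.1036C>T":
        "2/14598 2/12414 2/8362 0/4052 0/2184 " + _Z,
    "ASPH:c.2203C>T":
        "1/15190 1/13006 1/8600 0/4406 0/2184 " + _Z,
    "RAB23:c.434T>A":
        "6/15190 4/12994 2/8590 2/4404 2/2184 0/492 0/362 0/572 2/758 "
        "0/122 1/170 0/194 0/200 0/120 0/186 1/178 0/28 0/178 0/194 0/132 "
        "0/110 0/196 0/176",
    "NNT:c.1990G>A":
        "1/15190 1/13006 1/8600 0/4406 0/2184 " + _Z,
    "ADAR:c.577C>A":
        "43/15190 41/13006 32/8600 9/4406 2/2184 0/492 1/362 0/572 1/758 "
        "0/122 0/170 0/194 0/200 1/120 0/186 0/178 0/28 0/178 0/194 0/132 "
        "0/110 1/196 0/176",
    "SERAC1:c.1627_1628insTC":
        "1/14702 1/12518 1/8254 0/4264 0/2184 " + _Z,
}

# (disease, omim, gene, refseq_gene, mrna, hgvs_c, hgvs_p, rsid)
_PANEL_ROWS: list[tuple[str, str, str, str, str, str, str, str]] = [
    ("Sickle cell anemia", "#603903", "HBB", "NG_000007.3", "NM_000518.4",
     "c.20A>T", "p.Glu7Val", "rs77121243"),
    ("Primary immunodeficiency (Mucocutaneous fungal infection)", "#613108",
     "CLEC7A", "NG_016291.1", "NM_197947.2", "c.714T>G", "p.Tyr238*", "rs16910526"),
    ("Pituitary hormone deficiency, combined 2", "#262600", "PROP1",
     "NG_015889.1", "NM_006261.4", "c.301_302delAG", "p.Leu102Cysfs*8", "rs193922688"),
    ("Canavan disease", "#271900", "ASPA", "NG_008399.1", "NM_000049.2",
     "c.854A>C", "p.Glu285Ala", "rs28940279"),
    ("Canavan disease", "#271900", "ASPA", "NG_008399.1", "NM_000049.2",
     "c.914C>A", "p.Ala305Glu", "rs28940574"),
    ("Pustular psoriasis", "", "AP1S3", "NG_034017.1", "NM_001039569.1",
     "c.11T>G", "p.Phe4Cys", "rs116107386"),
    ("Pustular psoriasis", "", "AP1S3", "NG_034017.1", "NM_001039569.1",
     "c.64A>G", "p.Thr22Ala", "rs149183052"),
    ("Pustular psoriasis", "", "AP1S3", "NG_034017.1", "NM_001039569.1",
     "c.95C>T", "p.Thr32Ile", "rs78536455"),
    ("Pustular psoriasis", "", "AP1S3", "NG_034017.1", "NM_001039569.1",
     "c.97C>T", "p.Arg33Trp", "rs138292988"),
    ("Rod-cone dystrophy", "#615780", "PLK1S1", "NG_033122.1", "NM_018474.4",
     "c.226C>T", "p.Arg76*", "rs202210819"),
    ("Primary autosomal recessive microcephaly 1", "#251200", "MCPH1",
     "NG_016619.1", "NM_024596.3", "c.74C>G", "p.Ser25*", "rs121434305"),
    ("Seckel syndrome 5", "#613823", "CEP152", "NG_027518.1", "NM_001194998.1",
     "c.2000A>G", "p.Lys667Arg", "rs200879436"),
    ("Seckel syndrome 5", "#613823", "CEP152", "NG_027518.1", "NM_001194998.1",
     "c.2034T>G", "p.Tyr678*", "rs182018947"),
    ("Pontocerebellar hypoplasia type 1B", "#614678", "EXOSC3", "NG_032780.1",
     "NM_001002269.1", "c.238G>T", "p.Val80Phe", "rs374550999"),
    ("Pontocerebellar hypoplasia type 1B", "#614678", "EXOSC3", "NG_032780.1",
     "NM_001002269.1", "c.395A>C", "p.Asp132Ala", "rs141138948"),
    ("Miller syndrome", "#263750", "DHODH", "NG_016271.1", "NM_001361.4",
     "c.475-1269A>G", "", "rs370087266"),
    ("Miller syndrome", "#263750", "DHODH", "NG_016271.1", "NM_001361.4",
     "c.403C>T", "p.Arg135Cys", "rs201230446"),
    ("Miller syndrome", "#263750", "DHODH", "NG_016271.1", "NM_001361.4",
     "c.454G>A", "p.Gly152Arg", "rs267606766"),
    ("Miller syndrome", "#263750", "DHODH", "NG_016271.1", "NM_001361.4",
     "c.1036C>T", "p.Arg346Trp", "rs201947120"),
    ("Traboulsi syndrome (FDLAB)", "#601552", "ASPH", "NG_013210.1",
     "NM_004318.3", "c.2203C>T", "p.Arg735Trp", "rs374385878"),
    ("Carpenter syndrome 1", "#201000", "RAB23", "NG_012170.1", "NM_016277.4",
     "c.434T>A", "p.Leu145*", "rs121908171"),
    ("Glucocorticoid deficiency 4", "#614736", "NNT", "NG_032869.1",
     "NM_012343.3", "c.1990G>A", "p.Gly664Arg", "rs371979800"),
    ("Aicardi-Goutieres syndrome 6", "#615010", "ADAR", "NG_011844.1",
     "NM_001111.4", "c.577C>A", "p.Pro193Ala", "rs145588689"),
    ("MEGDEL syndrome", "#614739", "SERAC1", "NG_032889.1", "NM_032861.3",
     "c.1627_1628insTC", "p.Ser543Phefs*44", ""),
]

# synthetic placeholder locus for the one rsID-less entry (see module docstring)
_SERAC1_LOCUS = Locus(chrom="6", pos=158_571_484, ref="A", alt="ATC")


def make_panel() -> DiseasePanel:
    """The 24-mutation detected panel (15 disorders), with rsIDs as keys."""
    entries = []
    for disease, omim, gene, refseq, mrna, hgvs_c, hgvs_p, rsid in _PANEL_ROWS:
        locus = _SERAC1_LOCUS if not rsid else None
        entries.append(
            MutationRecord(
                disease_name=disease, omim_id=omim, gene_symbol=gene,
                refseq_gene=refseq, mrna_id=mrna, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
                rsid=rsid, locus=locus,
            )
        )
    return DiseasePanel(entries=entries, name="detected-24", version="1")


def make_table1_fixture(panel: DiseasePanel | None = None) -> list[SiteObservation]:
    """The full printed carrier table as SiteObservations (24 × 23 cells)."""
    panel = panel if panel is not None else make_panel()
    out: list[SiteObservation] = []
    for key, cells in _CARRIER_TABLE.items():
        parts = cells.split()
        assert len(parts) == len(_ROW_ORDER), key
        rec = panel.by_key(key)
        for (pop, cohort), cell in zip(_ROW_ORDER, parts):
            ac, an = cell.split("/")
            out.append(
                SiteObservation(
                    mutation_key=key, population=pop, cohort=cohort,
                    ac=int(ac), an=int(an), record=rec,
                )
            )
    return out


#: SCA literature allele frequencies (clinical prevalence surveys / HbS maps);
#: a (low, high) range per population, single values stored as a degenerate range.
SCA_REFERENCE_AF: list[tuple[str, str, float, float, str]] = [
    ("AA", "NHLBI", 0.0447, 0.0577, "CDC"),
    ("AFR", "1000G", 0.0447, 0.0577, "CDC"),
    ("AMR", "1000G", 0.00527, 0.0316, "CDC;Morton2013"),
    ("ASN", "1000G", 0.0, 0.0, "Modell2008;Piel2013"),
    ("ASW", "1000G", 0.0447, 0.0577, "CDC"),
    ("CHB", "1000G", 0.0, 0.0, "Piel2013"),
    ("CHS", "1000G", 0.0, 0.0, "Piel2013"),
    ("CLM", "1000G", 0.008, 0.008, "Piel2013"),
    ("FIN", "1000G", 0.0, 0.0, "Piel2013"),
    ("GBR", "1000G", 0.009, 0.009, "Piel2013"),
    ("IBS", "1000G", 0.007, 0.007, "Piel2013"),
    ("JPT", "1000G", 0.0, 0.0, "Piel2013"),
    ("LWK", "1000G", 0.038, 0.038, "Piel2013"),
    ("MXL", "1000G", 0.007, 0.007, "Piel2013"),
    ("PUR", "1000G", 0.004, 0.004, "Piel2013"),
    ("TSI", "1000G", 0.005, 0.005, "Piel2013"),
    ("YRI", "1000G", 0.171, 0.171, "Piel2013"),
]


def make_sca_reference() -> list[tuple[str, str, float, float, str]]:
    """Literature SCA allele-frequency reference rows (population, cohort, low, high, source)."""
    return list(SCA_REFERENCE_AF)


#: A few cells from the 60,706-individual aggregation cohort ("ExAC") summary
#: table, as printed; used to exercise printed-table ingestion at a second scale.
EXAC_OBSERVATIONS: list[tuple[str, str, int, int]] = [
    ("HBB:c.20A>T", "African", 505, 10404),
    ("CLEC7A:c.714T>G", "African", 253, 10404),
    ("CLEC7A:c.714T>G", "Latino", 395, 11578),
]


def make_exac_fixture(panel: DiseasePanel | None = None) -> list[SiteObservation]:
    panel = panel if panel is not None else make_panel()
    return [
        SiteObservation(
            mutation_key=k, population=pop, cohort="ExAC", ac=ac, an=an,
            record=panel.by_key(k),
        )
        for k, pop, ac, an in EXAC_OBSERVATIONS
    ]
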