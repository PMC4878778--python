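"""Disease-mutation panel registry.

A panel is the curated list of causative mutations for a set of recessive
disorders: one row per mutation carrying the disease, gene, transcript
annotations (RefSeqGene / mRNA accessions, HGVS c. and p.), a dbSNP rsID
and/or an explicit genomic locus.  The registry loads and validates panels
(TSV or JSON), and matches variants observed in cohort VCFs back to panel
entries.  Matching is locus-first with rsID as fallback; indel alleles are
reduced to a canonical left-aligned minimal spelling before comparison so
that equivalent spellings of the same deletion/insertion collide.

Genome build is carried as opaque metadata; no liftover is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import (
    AlleleNormalizationError,
    AmbiguousMatchError,
    PanelParseError,
    PanelValidationError,
)

_VALID_BASES = frozenset("ACGT")

PANEL_COLUMNS = [
    "disease_name",
    "omim_id",
    "gene_symbol",
    "refseq_gene",
    "mrna_id",
    "hgvs_c",
    "hgvs_p",
    "rsid",
    "chrom",
    "pos",
    "ref",
    "alt",
]


@dataclass(frozen=True)
class Locus:
    """A 1-based genomic location with explicit ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelValidationError(f"locus position must be 1-based positive, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise PanelValidationError(
                    f"{name} allele {allele!r} is not a non-empty string over A/C/G/T"
                )


@dataclass(frozen=True)
class MutationRecord:
    """One panel entry: a single causative mutation for one disorder."""

    disease_name: str
    gene_symbol: str
    hgvs_c: str
    hgvs_p: str = ""
    omim_id: str = ""
    refseq_gene: str = ""
    mrna_id: str = ""
    rsid: str = ""
    locus: Optional[Locus] = None
    inheritance: str = "autosomal-recessive"

    def __post_init__(self) -> None:
        if not self.rsid and self.locus is None:
            raise PanelValidationError(
                f"{self.disease_name} {self.hgvs_c}: need at least one of rsid or locus"
            )

    @property
    def key(self) -> str:
        """Stable identifier used in observation tables: GENE:hgvs_c."""
        return f"{self.gene_symbol}:{self.hgvs_c}"


def normalize_allele_pair(
    pos: int,
    ref: str,
    alt: str,
    reference_context: str,
    context_start: int = 1,
) -> tuple[int, str, str]:
    """Reduce (pos, ref, alt) to the canonical left-aligned minimal spelling.

    ``reference_context`` is the reference sequence covering the variant;
    ``context_start`` is the 1-based coordinate of its first base.  The
    procedure is the standard variant-normalisation algorithm: trim shared
    suffix, trim shared prefix, then shift pure indels leftwards while the
    trailing base of the longer allele equals the reference base preceding
    the variant.  The result is idempotent.

    Raises
    ------
    AlleleNormalizationError
        if ref == alt, or ref disagrees with the reference context.
    """
    if ref == alt:
        raise AlleleNormalizationError(f"ref and alt identical ({ref!r}) at pos {pos}")
    if not ref or not alt:
        raise AlleleNormalizationError("empty allele before normalization; pad from context")

    offset = pos - context_start
    if offset < 0 or offset + len(ref) > len(reference_context):
        raise AlleleNormalizationError(
            f"variant at pos {pos} (ref {ref!r}) not covered by reference context"
        )
    if reference_context[offset : offset + len(ref)] != ref:
        raise AlleleNormalizationError(
            f"ref {ref!r} at pos {pos} disagrees with reference context "
            f"{reference_context[offset:offset + len(ref)]!r}"
        )

    # right-trim shared suffix; when an allele empties, extend left from the
    # reference context (this is what shifts indels leftwards through repeats)
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos - 1 < context_start:
                raise AlleleNormalizationError(
                    f"reference context too short to left-align variant at pos {pos}"
                )
            pos -= 1
            prev = reference_context[pos - context_start]
            ref, alt = prev + ref, prev + alt
        elif ref[-1] != alt[-1]:
            break
    # left-trim shared prefix down to minimal representation
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Context-free minimal spelling: trim shared suffix then prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class DiseasePanel:
    """An ordered, validated collection of mutation records."""

    entries: list[MutationRecord]
    name: str = "panel"
    version: str = ""
    genome_build: str = ""

    _by_locus: dict[tuple[str, int, str, str], list[MutationRecord]] = field(
        init=False, repr=False, default_factory=dict
    )
    _by_rsid: dict[str, list[MutationRecord]] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise PanelValidationError(f"panel {self.name!r} is empty")
        seen: set[tuple[str, str]] = set()
        for rec in self.entries:
            k = (rec.disease_name, rec.hgvs_c)
            if k in seen:
                raise PanelValidationError(f"duplicate panel entry (disease, hgvs_c) = {k}")
            seen.add(k)
        rsid_locus: dict[str, Locus] = {}
        for rec in self.entries:
            if rec.rsid:
                self._by_rsid.setdefault(rec.rsid, []).append(rec)
                if rec.locus is not None:
                    prior = rsid_locus.get(rec.rsid)
                    if prior is not None and prior != rec.locus:
                        raise PanelValidationError(
                            f"rsid {rec.rsid} maps to two different loci in panel"
                        )
                    rsid_locus[rec.rsid] = rec.locus
            if rec.locus is not None:
                lk = self._locus_key(rec.locus.chrom, rec.locus.pos, rec.locus.ref, rec.locus.alt)
                self._by_locus.setdefault(lk, []).append(rec)

    @staticmethod
    def _locus_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
        pos, ref, alt = _trim(pos, ref, alt)
        return (_norm_chrom(chrom), pos, ref, alt)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.entries)

    @property
    def diseases(self) -> list[str]:
        out: list[str] = []
        for rec in self.entries:
            if rec.disease_name not in out:
                out.append(rec.disease_name)
        return out

    def by_key(self, key: str) -> MutationRecord:
        for rec in self.entries:
            if rec.key == key:
                return rec
        raise KeyError(key)

    def match_variant(
        self,
        chrom: Optional[str] = None,
        pos: Optional[int] = None,
        ref: Optional[str] = None,
        alt: Optional[str] = None,
        rsid: Optional[str] = None,
    ) -> Optional[MutationRecord]:
        """Match an observed variant to a panel record, or return None.

        Locus match (after context-free minimal-spelling reduction on both
        sides) takes precedence; rsID is the fallback.  Two panel entries
        matching one variant is an AmbiguousMatchError, never a silent pick.
        Callers should left-align indels with :func:`normalize_allele_pair`
        first when a reference context is available.
        """
        hits: list[MutationRecord] = []
        has_locus_query = chrom is not None and pos is not None and bool(ref) and bool(alt)
        if has_locus_query:
            hits = self._by_locus.get(self._locus_key(chrom, pos, ref, alt), [])
        if not hits and rsid:
            hits = self._by_rsid.get(rsid, [])
            if has_locus_query:
                # locus wins: a record with its own locus that failed the locus
                # lookup must not be resurrected by a shared rsID (multi-allelic
                # decomposition produces sibling alts carrying the same rsID)
                hits = [r for r in hits if r.locus is None]
        if not hits:
            return None
        if len(hits) > 1:
            raise AmbiguousMatchError(
                f"variant matches {len(hits)} panel entries: "
                + ", ".join(r.key for r in hits)
            )
        return hits[0]


def _record_from_row(row: dict[str, str], rownum: int) -> MutationRecord:
    def get(col: str) -> str:
        v = (row.get(col) or "").strip()
        return "" if v in {"-", ".", "NA"} else v

    locus = None
    if get("chrom") and get("pos"):
        try:
            pos = int(get("pos"))
        except ValueError as exc:
            raise PanelParseError(f"row {rownum}: field 'pos' is not an integer: {row['pos']!r}") from exc
        try:
            locus = Locus(get("chrom"), pos, get("ref").upper(), get("alt").upper())
        except PanelValidationError as exc:
            raise PanelParseError(f"row {rownum}: {exc}") from exc
    if not get("disease_name"):
        raise PanelParseError(f"row {rownum}: field 'disease_name' is empty")
    if not get("hgvs_c"):
        raise PanelParseError(f"row {rownum}: field 'hgvs_c' is empty")
    try:
        return MutationRecord(
            disease_name=get("disease_name"),
            omim_id=get("omim_id"),
            gene_symbol=get("gene_symbol"),
            refseq_gene=get("refseq_gene"),
            mrna_id=get("mrna_id"),
            hgvs_c=get("hgvs_c"),
            hgvs_p=get("hgvs_p"),
            rsid=get("rsid"),
            locus=locus,
        )
    except PanelValidationError as exc:
        raise PanelParseError(f"row {rownum}: {exc}") from exc


def load_panel(path: str | Path, format: Optional[str] = None) -> DiseasePanel:
    """Load and validate a panel from TSV or JSON.

    The TSV carries one column per PANEL_COLUMNS entry; the JSON form is
    ``{"name":…, "version":…, "genome_build":…, "entries":[{col: value}…]}``.
    Format is inferred from the suffix when not given.  Rows failing the
    record invariants raise with row-level diagnostics.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    text = path.read_text()
    if not text.strip():
        raise PanelParseError(f"{path}: file is empty")
    name, version, build = path.stem, "", ""
    rows: list[dict[str, str]]
    if format == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise PanelParseError(f"{path}: invalid JSON: {exc}") from exc
        name = doc.get("name", name)
        version = doc.get("version", "")
        build = doc.get("genome_build", "")
        rows = [{k: str(v) if v is not None else "" for k, v in e.items()} for e in doc.get("entries", [])]
    elif format == "tsv":
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("##")]
        header = lines[0].lstrip("#").rstrip("\n").split("\t")
        missing = [c for c in ("disease_name", "hgvs_c") if c not in header]
        if missing:
            raise PanelParseError(f"{path}: header missing required columns {missing}")
        rows = []
        for ln in lines[1:]:
            vals = ln.rstrip("\n").split("\t")
            rows.append(dict(zip(header, vals)))
    else:
        raise ValueError(f"unknown panel format {format!r}")
    if not rows:
        raise PanelParseError(f"{path}: no panel rows")
    entries = [_record_from_row(row, i + 2) for i, row in enumerate(rows)]
    return DiseasePanel(entries=entries, name=name, version=version, genome_build=build)


def save_panel(panel: DiseasePanel, path: str | Path, format: Optional[str] = None) -> None:
    """Serialise a panel to TSV or JSON; round-trips losslessly with load_panel."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    rows = []
    for rec in panel:
        row = {
            "disease_name": rec.disease_name,
            "omim_id": rec.omim_id,
            "gene_symbol": rec.gene_symbol,
            "refseq_gene": rec.refseq_gene,
            "mrna_id": rec.mrna_id,
            "hgvs_c": rec.hgvs_c,
            "hgvs_p": rec.hgvs_p,
            "rsid": rec.rsid,
            "chrom": rec.locus.chrom if rec.locus else "",
            "pos": str(rec.locus.pos) if rec.locus else "",
            "ref": rec.locus.ref if rec.locus else "",
            "alt": rec.locus.alt if rec.locus else "",
        }
        rows.append(row)
    if format == "json":
        doc = {
            "name": panel.name,
            "version": panel.version,
            "genome_build": panel.genome_build,
            "entries": rows,
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    else:
        lines = ["\t".join(PANEL_COLUMNS)]
        lines += ["\t".join(row[c] for c in PANEL_COLUMNS) for row in rows]
        path.write_text("\n".join(lines) + "\n")


def panel_from_records(records: Iterable[MutationRecord], name: str = "panel", **kw) -> DiseasePanel:
    return DiseasePanel(entries=list(records), name=name, **kw)
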