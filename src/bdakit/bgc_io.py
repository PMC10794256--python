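"""Read and post-process biosynthetic gene cluster (BGC) annotations.

This module turns antiSMASH-dialect GenBank output and MIBiG-style JSON
metadata into :class:`BGCRecord` objects, applies the standard
post-processing rules (short-contig filtering, region trimming,
contig-edge flagging, product-to-class mapping, qualifier precedence)
and emits biosynthetic domain architectures (BDAs): the ordered sequence
of biosynthetic domain labels of a cluster.

Coordinates are 0-based half-open internally; GenBank coordinates
(1-based closed) are converted at the I/O boundary, which Biopython
already does for us.
"""

from __future__ import annotations

import io
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO

__all__ = [
    "DomainCall",
    "BGCRecord",
    "BDA",
    "FilterConfig",
    "BGCParseError",
    "normalize_label",
    "parse_antismash_genbank",
    "map_product_to_class",
    "resolve_feature_precedence",
    "trim_region",
    "flag_contig_edge",
    "filter_short_contigs",
    "parse_mibig_json",
    "classify_reference",
    "build_bda",
    "write_bgc_table",
    "write_bda_table",
    "read_bda_table",
]

MODULAR_CLASSES = ("NRPS", "modular_PKS")
BGC_CLASSES = ("NRPS", "modular_PKS", "typeIII_PKS", "TPS", "other")

#: Canonical domain vocabulary aliases.  antiSMASH symbols differ between the
#: ``NRPS_PKS`` and ``sec_met_domain`` qualifier dialects; both are folded onto
#: the short field-standard symbols used throughout the package.
LABEL_ALIASES = {
    "Condensation_LCL": "Cond_LCL",
    "Condensation_DCL": "Cond_DCL",
    "Condensation_Starter": "Cond_Starter",
    "Condensation_Dual": "Cond_Dual",
    "Cglyc": "Cond_Cglyc",
    "AMP-binding": "AMP_binding",
    "PP-binding": "PP_bind",
    "PP_binding": "PP_bind",
    "PKS_PP": "PP_bind",
    "Thioesterase": "TE",
    "PKS_TE": "TE",
    "PKS_AT": "AT",
    "PKS_KR": "KR",
    "PKS_DH": "DH",
    "PKS_DH2": "DH",
    "PKS_ER": "ER",
    "PKS_KS(Iterative-KS)": "Itr_KS",
    "PKS_KS(Modular-KS)": "Mod_KS",
    "PKS_KS(Hybrid-KS)": "Hyb_KS",
    "PKS_KS(Trans-AT-KS)": "Trans_AT_KS",
    "Iterative-KS": "Itr_KS",
    "Modular-KS": "Mod_KS",
    "Hybrid-KS": "Hyb_KS",
    "Trans-AT-KS": "Trans_AT_KS",
    "NAD_binding_4": "NAD_bind_4",
    "Chal_sti_synt_N": "Chal_sti_synt_N",
    "Chal_sti_synt_C": "Chal_sti_synt_C",
}

#: Labels that mark an iterative ketosynthase; their presence re-classifies an
#: NRPS/PKS hybrid candidate as modular PKS.
ITERATIVE_KS_LABELS = frozenset({"Itr_KS"})

_SEPARATOR_RE = re.compile(r"[ \t]+")


class BGCParseError(ValueError):
    """Raised when a GenBank or MIBiG input cannot be parsed."""


def normalize_label(raw: str) -> str:
    """Normalize a domain symbol to the canonical vocabulary.

    Strips whitespace, unifies internal whitespace separators to
    underscores (case is preserved) and applies the alias table, so e.g.
    ``"PP-binding"`` and ``"PP_binding"`` both become ``"PP_bind"``.
    """
    label = _SEPARATOR_RE.sub("_", raw.strip())
    if not label:
        raise ValueError("empty domain label")
    return LABEL_ALIASES.get(label, label)


@dataclass(frozen=True)
class DomainCall:
    """One biosynthetic domain annotated on a CDS."""

    label: str
    cds_id: str
    strand: str  # "+" or "-"
    start: int  # genomic, 0-based
    end: int  # genomic, exclusive
    source_feature: str  # "NRPS_PKS" or "sec_met_domain"
    rank_in_cds: int  # ordinal in translation order

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("DomainCall.label must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"DomainCall: start {self.start} >= end {self.end}")
        if self.rank_in_cds < 0:
            raise ValueError("DomainCall.rank_in_cds must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.source_feature not in ("NRPS_PKS", "sec_met_domain"):
            raise ValueError(f"invalid source_feature {self.source_feature!r}")


@dataclass
class BGCRecord:
    """One detected (candidate) or database (reference) gene cluster."""

    bgc_id: str
    contig_id: str
    contig_length: int
    bgc_class: str
    subclass: list[str]
    region_start: int
    region_end: int
    contig_edge: bool = False
    role: str = "candidate"
    domains: list[DomainCall] = field(default_factory=list)
    evidence: list[str] = field(default_factory=list)
    chem_acts: list[str] = field(default_factory=list)
    organism: str = "unknown"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.region_start < self.region_end:
            raise ValueError(
                f"{self.bgc_id}: region_start {self.region_start} >= "
                f"region_end {self.region_end}"
            )
        if self.bgc_class not in BGC_CLASSES:
            raise ValueError(f"{self.bgc_id}: unknown class {self.bgc_class!r}")
        if self.role not in ("candidate", "reference"):
            raise ValueError(f"{self.bgc_id}: unknown role {self.role!r}")


@dataclass(frozen=True)
class BDA:
    """Biosynthetic domain architecture: ordered domain labels of one BGC."""

    bgc_id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class FilterConfig:
    """Post-processing thresholds: minimum contig length and edge margin."""

    min_contig_length: int = 10_000
    edge_margin: int = 20_000

    def __post_init__(self) -> None:
        if self.min_contig_length <= 0 or self.edge_margin <= 0:
            raise ValueError("FilterConfig values must be > 0")


# ---------------------------------------------------------------------------
# GenBank parsing (antiSMASH region dialect)
# ---------------------------------------------------------------------------

_NRPS_PKS_DOMAIN_RE = re.compile(r"^Domain:\s*([^(]+?)\s*\((\d+)-(\d+)\)")
_SEC_MET_DOMAIN_RE = re.compile(r"^([^(]+?)\s*\(")


def _cds_id(feature, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"cds_{index}"


def parse_antismash_genbank(
    source: Union[str, TextIO],
) -> list[BGCRecord]:
    """Parse antiSMASH region GenBank output into BGC records.

    Each ``region`` feature yields one :class:`BGCRecord`; biosynthetic
    domains are collected from ``NRPS_PKS`` (``Domain: X (a-b). ...``
    entries, protein coordinates) and ``sec_met_domain`` (``X (E-value:
    ...)`` entries) CDS qualifiers.  Both qualifier kinds are retained
    here; class-dependent precedence is applied separately by
    :func:`resolve_feature_precedence`.  Records whose region carries no
    ``product`` qualifier get class ``other`` and a warning; records
    without any biosynthetic domain are flagged ``no_domains``.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    try:
        seq_records = list(SeqIO.parse(handle, "genbank"))
    except ValueError as exc:
        raise BGCParseError(f"malformed GenBank input: {exc}") from exc
    if not seq_records:
        raise BGCParseError("malformed GenBank input: no LOCUS record found")

    records: list[BGCRecord] = []
    for seq_record in seq_records:
        contig_id = seq_record.id
        contig_length = len(seq_record)
        regions = [f for f in seq_record.features if f.type == "region"]
        cds_features = [f for f in seq_record.features if f.type == "CDS"]
        for ri, region in enumerate(regions, start=1):
            number = region.qualifiers.get("region_number", [str(ri)])[0]
            bgc_id = f"{contig_id}_{number}"
            products = [str(p) for p in region.qualifiers.get("product", [])]
            if not products:
                warnings.warn(
                    f"{bgc_id}: region has no 'product' qualifier; class set to other",
                    stacklevel=2,
                )
            rstart = int(region.location.start)
            rend = int(region.location.end)
            domains: list[DomainCall] = []
            for ci, cds in enumerate(cds_features):
                cstart, cend = int(cds.location.start), int(cds.location.end)
                if cend <= rstart or cstart >= rend:
                    continue
                domains.extend(_parse_cds_domains(cds, ci))
            bgc_class = map_product_to_class(products) if products else "other"
            record = BGCRecord(
                bgc_id=bgc_id,
                contig_id=contig_id,
                contig_length=contig_length,
                bgc_class=bgc_class,
                subclass=products,
                region_start=rstart,
                region_end=rend,
                domains=domains,
            )
            if not domains:
                record.flags.append("no_domains")
            records.append(record)
    return records


def _parse_cds_domains(cds, cds_index: int) -> list[DomainCall]:
    """Extract domain calls of one CDS, ordered in translation order."""
    cds_id = _cds_id(cds, cds_index)
    strand = "-" if cds.location.strand == -1 else "+"
    cstart, cend = int(cds.location.start), int(cds.location.end)
    calls: list[tuple[int, str, int, int, str]] = []  # (order, label, gs, ge, kind)

    for entry in cds.qualifiers.get("NRPS_PKS", []):
        m = _NRPS_PKS_DOMAIN_RE.match(str(entry).strip())
        if m is None:  # "type: ..." and other non-domain entries
            continue
        label = normalize_label(m.group(1))
        ps, pe = int(m.group(2)), int(m.group(3))
        if strand == "+":
            gs, ge = cstart + 3 * ps, cstart + 3 * pe
        else:
            gs, ge = cend - 3 * pe, cend - 3 * ps
        calls.append((ps, label, gs, ge, "NRPS_PKS"))

    for k, entry in enumerate(cds.qualifiers.get("sec_met_domain", [])):
        m = _SEC_MET_DOMAIN_RE.match(str(entry).strip())
        if m is None:
            raise BGCParseError(
                f"{cds_id}: cannot parse sec_met_domain qualifier {entry!r}"
            )
        label = normalize_label(m.group(1))
        # No within-protein coordinates in this dialect: span the CDS and
        # keep listing order as translation order.
        calls.append((k, label, cstart, cend, "sec_met_domain"))

    calls.sort(key=lambda c: (c[4], c[0]))  # stable per qualifier kind
    out = []
    rank = {"NRPS_PKS": 0, "sec_met_domain": 0}
    for _, label, gs, ge, kind in calls:
        out.append(
            DomainCall(
                label=label,
                cds_id=cds_id,
                strand=strand,
                start=gs,
                end=ge,
                source_feature=kind,
                rank_in_cds=rank[kind],
            )
        )
        rank[kind] += 1
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

_CANDIDATE_SUBCLASS_MAP = {
    "NRPS": "NRPS",
    "NRPS-like": "NRPS",
    "T1PKS": "modular_PKS",
    "T2PKS": "modular_PKS",
    "T3PKS": "typeIII_PKS",
    "terpene": "TPS",
}

#: Priority when a region carries several product labels (hybrids resolve to
#: the highest-priority class unless an iterative KS forces modular PKS).
_CLASS_PRIORITY = ("NRPS", "modular_PKS", "typeIII_PKS", "TPS", "other")


def map_product_to_class(
    subclasses: Sequence[str],
    domain_labels: Iterable[str] = (),
) -> str:
    """Map antiSMASH ``product`` labels to one of the five BGC classes.

    ``NRPS``/``NRPS-like`` products map to NRPS, ``T1PKS``/``T2PKS`` to
    modular PKS, ``T3PKS`` to type III PKS and ``terpene`` to TPS;
    everything else is ``other``.  Mixed products resolve by the priority
    NRPS > modular_PKS > typeIII_PKS > TPS > other, except that an
    NRPS/PKS hybrid carrying an iterative-KS domain is classified as
    modular PKS.
    """
    if not subclasses:
        raise ValueError("subclasses must be nonempty")
    mapped = {_CANDIDATE_SUBCLASS_MAP.get(s, "other") for s in subclasses}
    if (
        "NRPS" in mapped
        and "modular_PKS" in mapped
        and ITERATIVE_KS_LABELS.intersection(domain_labels)
    ):
        return "modular_PKS"
    for cls in _CLASS_PRIORITY:
        if cls in mapped:
            return cls
    return "other"


def classify_reference(
    biosyn_class: Sequence[str], subclass: Sequence[str]
) -> set[str]:
    """Map MIBiG class/subclass annotations to (non-exclusive) BGC classes.

    ``NRP`` entries map to NRPS and ``Terpene`` entries to TPS.
    ``Polyketide`` entries map to type III PKS when their only PKS
    subclass is "Type III", and to modular PKS when they carry any other
    PKS subclass (or none at all).
    """
    classes: set[str] = set()
    if "NRP" in biosyn_class:
        classes.add("NRPS")
    if "Terpene" in biosyn_class:
        classes.add("TPS")
    if "Polyketide" in biosyn_class:
        norm = {s.strip().lower().replace("-", " ") for s in subclass}
        if norm and norm <= {"type iii"}:
            classes.add("typeIII_PKS")
        else:
            classes.add("modular_PKS")
    return classes


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

#: Which qualifier kind wins, per class, at CDS loci annotated by both.
_PREFERRED_FEATURE = {
    "NRPS": "NRPS_PKS",
    "modular_PKS": "NRPS_PKS",
    "typeIII_PKS": "sec_met_domain",
    "TPS": "sec_met_domain",
    "other": "sec_met_domain",
}


def resolve_feature_precedence(
    calls: Sequence[DomainCall], bgc_class: str
) -> list[DomainCall]:
    """Resolve NRPS_PKS vs sec_met_domain duplication per CDS.

    At CDS loci carrying both qualifier kinds only the kind preferred for
    the record's class is kept (NRPS_PKS for modular classes,
    sec_met_domain otherwise); loci with a single kind are kept as-is.
    """
    preferred = _PREFERRED_FEATURE[bgc_class]
    kinds_per_cds: dict[str, set[str]] = {}
    for c in calls:
        kinds_per_cds.setdefault(c.cds_id, set()).add(c.source_feature)
    out = []
    for c in calls:
        if len(kinds_per_cds[c.cds_id]) > 1 and c.source_feature != preferred:
            continue
        out.append(c)
    return out


def trim_region(record: BGCRecord) -> BGCRecord:
    """Trim the region to the span of domain-bearing CDSs.

    Region bounds become the minimum start / maximum end over CDSs that
    contain at least one biosynthetic domain.  Records with no domains
    are returned untrimmed with a ``no_domains`` flag.
    """
    if not record.domains:
        flags = record.flags if "no_domains" in record.flags else record.flags + ["no_domains"]
        return replace(record, flags=flags)
    start = min(d.start for d in record.domains)
    end = max(d.end for d in record.domains)
    return replace(record, region_start=start, region_end=end)


def flag_contig_edge(record: BGCRecord, config: FilterConfig = FilterConfig()) -> bool:
    """True iff the (trimmed) region overlaps a terminal edge margin.

    The 5' margin is ``[0, edge_margin)`` and the 3' margin is
    ``(contig_length - edge_margin, contig_length]``.
    """
    if record.contig_length is None or record.contig_length <= 0:
        raise ValueError(f"{record.bgc_id}: contig_length missing")
    m = config.edge_margin
    if record.region_start < m:
        return True
    if record.region_end > record.contig_length - m:
        return True
    return False


def filter_short_contigs(
    records: Sequence[BGCRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[BGCRecord], list[BGCRecord]]:
    """Partition records into (kept, removed) by minimum contig length.

    A record is removed when its contig is strictly shorter than
    ``min_contig_length``; input order is preserved on both sides.
    """
    kept, removed = [], []
    for r in records:
        (removed if r.contig_length < config.min_contig_length else kept).append(r)
    return kept, removed


def postprocess(
    records: Sequence[BGCRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[BGCRecord], list[BGCRecord]]:
    """Full candidate post-processing: filter, precedence, trim, edge-flag."""
    kept, removed = filter_short_contigs(records, config)
    out = []
    for r in kept:
        cls = map_product_to_class(r.subclass, [d.label for d in r.domains]) if r.subclass else "other"
        r = replace(r, bgc_class=cls, domains=resolve_feature_precedence(r.domains, cls))
        r = trim_region(r)
        r = replace(r, contig_edge=flag_contig_edge(r, config))
        out.append(r)
    return out, removed


# ---------------------------------------------------------------------------
# MIBiG-style JSON
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MIBiGRejection:
    """Why a MIBiG entry was excluded from the reference set."""

    accession: str
    reason: str


def parse_mibig_json(
    source: Union[str, TextIO, dict],
) -> Union[list[BGCRecord], MIBiGRejection]:
    """Parse one MIBiG-style JSON entry into reference BGC record(s).

    An entry is accepted iff its locus completeness is ``"complete"``
    and it lists at least one piece of experimental evidence; accepted
    entries yield one record per assigned BGC class (class labels are
    non-exclusive), or a single ``other``-class record when no major
    class applies.  Rejections are returned as :class:`MIBiGRejection`
    with the reason.
    """
    if isinstance(source, dict):
        data = source
    elif isinstance(source, str):
        try:
            data = json.loads(source)
        except json.JSONDecodeError as exc:
            raise BGCParseError(f"unparsable MIBiG JSON: {exc}") from exc
    else:
        try:
            data = json.load(source)
        except json.JSONDecodeError as exc:
            raise BGCParseError(f"unparsable MIBiG JSON: {exc}") from exc

    cluster = data.get("cluster", data)
    accession = cluster.get("mibig_accession", "unknown_accession")
    loci = cluster.get("loci", {})
    if "completeness" not in loci:
        return MIBiGRejection(accession, "missing completeness field")
    if str(loci["completeness"]).lower() != "complete":
        return MIBiGRejection(accession, f"completeness={loci['completeness']}")
    evidence = [str(e) for e in loci.get("evidence", [])]
    if not evidence:
        return MIBiGRejection(accession, "no experimental evidence")

    biosyn_class = [str(c) for c in cluster.get("biosyn_class", [])]
    subclasses: list[str] = []
    for synth in cluster.get("polyketide", {}).get("synthases", []):
        subclasses.extend(str(s) for s in synth.get("subclass", []))
    chem_acts: list[str] = []
    for compound in cluster.get("compounds", []):
        for act in compound.get("chem_acts", []):
            if isinstance(act, dict):  # MIBiG 3.x: {"activity": ...}
                act = act.get("activity", "")
            if act:
                chem_acts.append(str(act))
    organism = str(cluster.get("organism_name") or "unknown")

    start = int(loci.get("start_coord", 1)) - 1
    end = int(loci.get("end_coord", start + 2))
    classes = classify_reference(biosyn_class, subclasses) or {"other"}
    records = []
    for cls in sorted(classes):
        records.append(
            BGCRecord(
                bgc_id=accession if len(classes) == 1 else f"{accession}|{cls}",
                contig_id=str(loci.get("accession", accession)),
                contig_length=max(end, 1),
                bgc_class=cls,
                subclass=subclasses,
                region_start=max(start, 0),
                region_end=end,
                role="reference",
                evidence=evidence,
                chem_acts=chem_acts,
                organism=organism,
            )
        )
    return records


# ---------------------------------------------------------------------------
# BDA construction
# ---------------------------------------------------------------------------


def build_bda(record: BGCRecord) -> BDA:
    """Emit the record's biosynthetic domain architecture.

    CDSs are ordered by genomic start; within each CDS, domains follow
    translation order (``rank_in_cds``), i.e. reverse genomic order on
    the minus strand.  Labels are already canonical at parse time.
    Modular-class records without domains are an error.
    """
    if not record.domains:
        if record.bgc_class in MODULAR_CLASSES:
            raise ValueError(
                f"{record.bgc_id}: modular-class record has no biosynthetic domains"
            )
        return BDA(record.bgc_id, ())
    cds_order: dict[str, int] = {}
    for d in record.domains:
        cds_order[d.cds_id] = min(cds_order.get(d.cds_id, d.start), d.start)
    ordered = sorted(
        record.domains, key=lambda d: (cds_order[d.cds_id], d.cds_id, d.rank_in_cds)
    )
    return BDA(record.bgc_id, tuple(normalize_label(d.label) for d in ordered))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_bgc_table(records: Sequence[BGCRecord], handle: TextIO) -> None:
    """Write the BGC summary table (TSV)."""
    handle.write(
        "bgc_id\tcontig_id\tcontig_length\tclass\tsubclass\tstart\tend\t"
        "contig_edge\trole\tn_domains\n"
    )
    for r in records:
        handle.write(
            f"{r.bgc_id}\t{r.contig_id}\t{r.contig_length}\t{r.bgc_class}\t"
            f"{','.join(r.subclass)}\t{r.region_start}\t{r.region_end}\t"
            f"{str(r.contig_edge).lower()}\t{r.role}\t{len(r.domains)}\n"
        )


def write_bda_table(bdas: Sequence[BDA], handle: TextIO) -> None:
    """Write BDAs as TSV: bgc_id, tab, comma-joined tokens."""
    handle.write("bgc_id\ttokens\n")
    for b in bdas:
        handle.write(f"{b.bgc_id}\t{','.join(b.tokens)}\n")


def read_bda_table(handle: TextIO) -> list[BDA]:
    """Read a BDA TSV written by :func:`write_bda_table`."""
    bdas = []
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("bgc_id\t"):
            continue
        bgc_id, _, tokens = line.partition("\t")
        bdas.append(BDA(bgc_id, tuple(t for t in tokens.split(",") if t)))
    return bdas
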