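"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: profile-HMM
families with a known homology structure, grammar-based BDAs built from
NRPS/PKS module grammars, antiSMASH-dialect GenBank records, MIBiG-style
JSON entries, and transporter layouts with controlled region densities.
All generators are deterministic per seed.

The module grammars mirror the canonical assembly-line architectures:
an NRPS elongation module is condensation-adenylation-carrier protein,
and an iterative PKS module is KS-AT-DH-ER-KR-carrier-NAD-binding.
Homology groups mirror the domain families that matter for alignment:
condensation subtypes, carrier proteins, and KS subtypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .bgc_io import BDA, BGCRecord, DomainCall
from .hmm_scoring import AMINO_ALPHABET, ProfileHMM, ScoringMatrix
from .transporter_context import REGIONS, RegionConfig, TransporterAnnotation, region_spans

__all__ = [
    "SimConfig",
    "HOMOLOGY_GROUPS",
    "NRPS_MODULE",
    "PKS_MODULE",
    "HYBRID_MODULE",
    "generate_phmm_family",
    "generate_phmm_families",
    "generate_bda",
    "perturb_bda",
    "generate_bda_families",
    "make_bgc_record",
    "generate_genbank",
    "generate_mibig_json",
    "generate_transporter_layout",
]

#: Domain homology groups used by fixtures (substitution classes).
HOMOLOGY_GROUPS: dict[str, tuple[str, ...]] = {
    "condensation": ("Cond_Starter", "Cond_DCL", "Cond_LCL", "Cond_Dual"),
    "carrier": ("PCP", "ACP", "PP_bind"),
    "ketosynthase": ("Hyb_KS", "Itr_KS", "Mod_KS", "Trans_AT_KS"),
    "adenylation": ("AMP_binding",),
    "thioesterase": ("TE",),
    "acyltransferase": ("AT",),
    "ketoreductase": ("KR",),
    "dehydratase": ("DH",),
    "enoylreductase": ("ER",),
    "nad_binding": ("NAD_bind_4",),
    "chalcone_synthase_n": ("Chal_sti_synt_N",),
    "chalcone_synthase_c": ("Chal_sti_synt_C",),
    "dimethylallyltransferase": ("dmat",),
    "protein_kinase": ("Pkinase",),
}

NRPS_MODULE = ("Cond_LCL", "AMP_binding", "PCP")
#: Canonical single iterative PKS module (7 domains).
PKS_MODULE = ("Itr_KS", "AT", "DH", "ER", "KR", "PP_bind", "NAD_bind_4")
HYBRID_MODULE = ("Hyb_KS", "AT", "KR", "PP_bind")
STARTER_UNIT = ("AMP_binding", "PCP")
TERMINATOR_UNIT = ("TE",)


def group_of(token: str) -> Optional[str]:
    for name, members in HOMOLOGY_GROUPS.items():
        if token in members:
            return name
    return None


def homology_matrix() -> ScoringMatrix:
    """Block scoring matrix over the fixture vocabulary: 1 within each
    homology group, -1 across groups."""
    return ScoringMatrix.from_groups(list(HOMOLOGY_GROUPS.values()))


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic generators."""

    seed: int = 0
    n_families: int = 3
    family_divergence: float = 0.2
    grammar: str = "NRPS"
    n_modules: int = 3
    sub_rate: float = 0.1
    del_rate: float = 0.0
    ins_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.family_divergence, self.sub_rate, self.del_rate, self.ins_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


# ---------------------------------------------------------------------------
# Profile-HMM families
# ---------------------------------------------------------------------------


def _point_mass(letter_idx: int) -> np.ndarray:
    col = np.zeros(len(AMINO_ALPHABET))
    col[letter_idx] = 1.0
    return col


def generate_phmm_family(
    labels: Sequence[str],
    ancestor_length: int,
    divergence: float,
    seed: int,
    letters: Optional[Sequence[int]] = None,
) -> list[ProfileHMM]:
    """One family of profiles derived from a common ancestor.

    The ancestor has point-mass match columns on ``letters`` (default:
    the whole alphabet); each member independently resamples each column
    with probability ``divergence``, so members share an expected
    fraction (1 - divergence) of the ancestor's columns.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    pool = np.array(letters if letters is not None else range(len(AMINO_ALPHABET)))
    ancestor = rng.choice(pool, size=ancestor_length)
    members = []
    for label in labels:
        cols = ancestor.copy()
        for i in range(ancestor_length):
            if rng.random() < divergence:
                alternatives = pool[pool != cols[i]]
                if alternatives.size:
                    cols[i] = rng.choice(alternatives)
        members.append(
            ProfileHMM(label, np.stack([_point_mass(c) for c in cols]))
        )
    return members


def generate_phmm_families(
    n_families: int,
    members_per_family: int = 3,
    ancestor_length: int = 12,
    divergence: float = 0.2,
    seed: int = 0,
) -> tuple[list[ProfileHMM], dict[str, int]]:
    """Several mutually unrelated families with within-family homology.

    Families draw their columns from disjoint alphabet subsets, so
    cross-family co-emission is exactly zero (matrix entries -1) while
    within-family entries are positive.  Returns (profiles, label ->
    family index truth).
    """
    if n_families > len(AMINO_ALPHABET):
        raise ValueError("at most 20 disjoint families")
    chunks = np.array_split(np.arange(len(AMINO_ALPHABET)), n_families)
    profiles: list[ProfileHMM] = []
    truth: dict[str, int] = {}
    for f in range(n_families):
        labels = [f"F{f}_m{k}" for k in range(members_per_family)]
        fam = generate_phmm_family(
            labels, ancestor_length, divergence, seed + 7919 * f, letters=chunks[f]
        )
        profiles.extend(fam)
        truth.update({lab: f for lab in labels})
    return profiles, truth


def carrier_protein_family(seed: int = 0, divergence: float = 0.15) -> list[ProfileHMM]:
    """A {PCP, ACP, PP_bind} family from one ancestor (mutually homologous)."""
    return generate_phmm_family(["PCP", "ACP", "PP_bind"], 10, divergence, seed)


# ---------------------------------------------------------------------------
# Grammar BDAs
# ---------------------------------------------------------------------------


def generate_bda(
    bgc_class: str,
    n_modules: int,
    bgc_id: str = "sim_bda",
    starter: bool = False,
    terminator: bool = False,
) -> BDA:
    """Grammar-based BDA: ``n_modules`` elongation modules plus optional
    starter (adenylation-carrier) and terminator (thioesterase) units."""
    modules = {"NRPS": NRPS_MODULE, "modular_PKS": PKS_MODULE, "hybrid": HYBRID_MODULE}
    if bgc_class not in modules:
        raise ValueError(f"unknown grammar class {bgc_class!r}")
    tokens: list[str] = []
    if starter:
        tokens.extend(STARTER_UNIT)
    if bgc_class == "hybrid":
        for k in range(n_modules):
            tokens.extend(NRPS_MODULE if k % 2 == 0 else HYBRID_MODULE)
    else:
        tokens.extend(modules[bgc_class] * n_modules)
    if terminator:
        tokens.extend(TERMINATOR_UNIT)
    return BDA(bgc_id, tuple(tokens))


def perturb_bda(
    bda: BDA,
    sub_rate: float = 0.1,
    del_rate: float = 0.0,
    ins_rate: float = 0.0,
    groups: Mapping[str, Sequence[str]] = HOMOLOGY_GROUPS,
    seed: int = 0,
    new_id: Optional[str] = None,
) -> BDA:
    """Perturb a BDA: substitutions within the token's homology group,
    deletions, and insertions of random vocabulary tokens."""
    rng = np.random.default_rng(seed)
    vocabulary = [t for members in groups.values() for t in members]
    tokens: list[str] = []
    for tok in bda.tokens:
        if del_rate and rng.random() < del_rate:
            continue
        if sub_rate and rng.random() < sub_rate:
            grp = next((m for m in groups.values() if tok in m), None)
            if grp is not None and len(grp) > 1:
                options = [t for t in grp if t != tok]
                tok = options[rng.integers(len(options))]
        tokens.append(tok)
        if ins_rate and rng.random() < ins_rate:
            tokens.append(vocabulary[rng.integers(len(vocabulary))])
    return BDA(new_id or bda.bgc_id, tuple(tokens))


#: Base architectures of the three recovery-test families: distinct module
#: counts/grammars keep between-family BDA similarity well below 0.8 while
#: within-group substitutions preserve full-length matches.
_FAMILY_BASES = (
    ("NRPS", 3, False, True),  # 10 tokens
    ("modular_PKS", 1, False, False),  # 7 tokens
    ("NRPS", 5, True, True),  # 18 tokens
)


def generate_bda_families(
    n_per_family: int = 20,
    sub_rate: float = 0.1,
    seed: int = 0,
    n_orphans: int = 2,
    with_references: bool = True,
) -> tuple[list[BDA], list[BDA], dict[str, str]]:
    """Candidate BDAs from 3 grammar families, plus references and truth.

    Family 0's base architecture is also emitted as a reference, so its
    members are expected "hit"; members of families 1-2 are expected
    "clustered"; ``n_orphans`` extra candidates carry unique
    architectures (expected "orphan").  Returns (candidates, references,
    candidate_id -> expected status).
    """
    candidates: list[BDA] = []
    references: list[BDA] = []
    truth: dict[str, str] = {}
    for f, (cls, mods, st, te) in enumerate(_FAMILY_BASES):
        base = generate_bda(cls, mods, f"family{f}_base", starter=st, terminator=te)
        expected = "clustered"
        if with_references and f == 0:
            references.append(BDA(f"ref_family{f}", base.tokens))
            expected = "hit"
        for k in range(n_per_family):
            member = perturb_bda(
                base, sub_rate=sub_rate, seed=seed + 104729 * f + k,
                new_id=f"family{f}_cand{k}",
            )
            candidates.append(member)
            truth[member.bgc_id] = expected
    # orphans: architectures unrelated to every family and to each other
    orphan_bases = [
        ("Chal_sti_synt_N", "Chal_sti_synt_C"),
        ("dmat", "TE", "dmat", "dmat", "TE", "dmat"),
    ]
    for k in range(n_orphans):
        tokens = orphan_bases[k % len(orphan_bases)] * (1 + k // len(orphan_bases))
        bda = BDA(f"orphan_cand{k}", tuple(tokens))
        candidates.append(bda)
        truth[bda.bgc_id] = "orphan"
    return candidates, references, truth


# ---------------------------------------------------------------------------
# GenBank records
# ---------------------------------------------------------------------------

_DOMAIN_NT = 300  # nucleotides per synthetic domain (100 codons)


def make_bgc_record(
    bgc_id: str,
    tokens: Sequence[str],
    contig_id: str = "ctg1",
    contig_length: int = 60_000,
    subclasses: Sequence[str] = ("NRPS",),
    region_start: int = 20_000,
    cds_split: Optional[Sequence[int]] = None,
    strands: Optional[Sequence[str]] = None,
    source_feature: str = "NRPS_PKS",
    role: str = "candidate",
) -> BGCRecord:
    """Construct a BGC record with synthetic domain coordinates.

    ``cds_split`` gives the number of domains per CDS (default: one CDS
    holding all tokens); ``strands`` one strand per CDS.  Domains occupy
    consecutive 300 bp blocks inside each CDS, in translation order
    (reverse genomic order on the minus strand), and CDSs are laid head
    to tail with 150 bp spacers from ``region_start``.
    """
    split = list(cds_split) if cds_split is not None else [len(tokens)]
    if sum(split) != len(tokens):
        raise ValueError("cds_split must sum to the number of tokens")
    strands = list(strands) if strands is not None else ["+"] * len(split)
    if len(strands) != len(split):
        raise ValueError("one strand per CDS required")
    domains: list[DomainCall] = []
    pos = region_start
    tok_iter = iter(tokens)
    for ci, (count, strand) in enumerate(zip(split, strands)):
        cds_start = pos
        cds_end = cds_start + count * _DOMAIN_NT
        cds_id = f"{bgc_id}_cds{ci}"
        for i in range(count):
            label = next(tok_iter)
            if strand == "+":
                gs = cds_start + i * _DOMAIN_NT
            else:
                gs = cds_end - (i + 1) * _DOMAIN_NT
            ge = gs + _DOMAIN_NT
            if source_feature == "sec_met_domain":
                gs, ge = cds_start, cds_end
            domains.append(
                DomainCall(
                    label=label,
                    cds_id=cds_id,
                    strand=strand,
                    start=gs,
                    end=ge,
                    source_feature=source_feature,
                    rank_in_cds=i,
                )
            )
        pos = cds_end + 150
    region_end = pos - 150
    if region_end + 150 > contig_length:
        raise ValueError("contig_length too short for the requested layout")
    return BGCRecord(
        bgc_id=bgc_id,
        contig_id=contig_id,
        contig_length=contig_length,
        bgc_class="other",
        subclass=list(subclasses),
        region_start=region_start,
        region_end=region_end,
        role=role,
        domains=domains,
    )


def generate_genbank(records: Sequence[BGCRecord]) -> str:
    """Serialize records as antiSMASH-dialect GenBank text.

    One LOCUS per contig; each record becomes a ``region`` feature and
    its CDSs carry ``NRPS_PKS`` (``Domain: X (a-b). ...``) and/or
    ``sec_met_domain`` (``X (E-value: ...)``) qualifiers.  Parsing the
    output through :func:`bdakit.bgc_io.parse_antismash_genbank`
    recovers the domain sequences and coordinates exactly.
    """
    import io as _io

    from Bio import SeqIO

    by_contig: dict[str, list[BGCRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)
    seq_records = []
    for contig_id, contig_records in by_contig.items():
        length = contig_records[0].contig_length
        seq_record = SeqRecord(
            Seq("A" * length), id=contig_id, name=contig_id[:16],
            description="synthetic contig",
            annotations={"molecule_type": "DNA"},
        )
        for ri, rec in enumerate(sorted(contig_records, key=lambda r: r.region_start), 1):
            region = SeqFeature(
                FeatureLocation(rec.region_start, rec.region_end),
                type="region",
                qualifiers={
                    "region_number": [str(ri)],
                    "product": list(rec.subclass),
                },
            )
            seq_record.features.append(region)
            cds_groups: dict[str, list[DomainCall]] = {}
            for d in rec.domains:
                cds_groups.setdefault(d.cds_id, []).append(d)
            for cds_id, calls in cds_groups.items():
                calls = sorted(calls, key=lambda d: d.rank_in_cds)
                strand = calls[0].strand
                if calls[0].source_feature == "sec_met_domain":
                    cstart = min(d.start for d in calls)
                    cend = max(d.end for d in calls)
                else:
                    cstart = min(d.start for d in calls)
                    cend = max(d.end for d in calls)
                quals: dict[str, list[str]] = {"locus_tag": [cds_id]}
                for d in calls:
                    if d.source_feature == "NRPS_PKS":
                        if strand == "+":
                            ps = (d.start - cstart) // 3
                            pe = (d.end - cstart) // 3
                        else:
                            ps = (cend - d.end) // 3
                            pe = (cend - d.start) // 3
                        quals.setdefault("NRPS_PKS", []).append(
                            f"Domain: {d.label} ({ps}-{pe}). E-value: 1e-10. Score: 50.0."
                        )
                    else:
                        quals.setdefault("sec_met_domain", []).append(
                            f"{d.label} (E-value: 1e-10, bitscore: 100.0, seeds: 10)"
                        )
                seq_record.features.append(
                    SeqFeature(
                        FeatureLocation(cstart, cend, strand=-1 if strand == "-" else 1),
                        type="CDS",
                        qualifiers=quals,
                    )
                )
        seq_records.append(seq_record)
    handle = _io.StringIO()
    SeqIO.write(seq_records, handle, "genbank")
    return handle.getvalue()


# ---------------------------------------------------------------------------
# MIBiG-style JSON
# ---------------------------------------------------------------------------


def generate_mibig_json(
    accession: str = "BGC0000001",
    completeness: str = "complete",
    evidence: Sequence[str] = ("Knock-out studies",),
    biosyn_class: Sequence[str] = ("NRP",),
    pks_subclasses: Sequence[str] = (),
    chem_acts: Sequence[str] = ("antibacterial",),
    compound: str = "compoundin",
    organism: Optional[str] = "Streptomyces sp.",
    start: int = 1,
    end: int = 45_000,
) -> str:
    """A MIBiG 3.x-shaped JSON entry as text."""
    cluster: dict = {
        "mibig_accession": accession,
        "biosyn_class": list(biosyn_class),
        "loci": {
            "accession": f"{accession}_locus",
            "completeness": completeness,
            "evidence": list(evidence),
            "start_coord": start,
            "end_coord": end,
        },
        "compounds": [
            {"compound": compound, "chem_acts": [{"activity": a} for a in chem_acts]}
        ],
    }
    if pks_subclasses:
        cluster["polyketide"] = {"synthases": [{"subclass": list(pks_subclasses)}]}
    if organism is not None:
        cluster["organism_name"] = organism
    return json.dumps({"cluster": cluster}, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Transporter layouts
# ---------------------------------------------------------------------------


def generate_transporter_layout(
    records: Sequence[BGCRecord],
    families: Sequence[str] = ("3.A.1", "2.A.1", "1.A.33"),
    density_per_kb: float = 0.3,
    factors: Optional[Mapping[tuple[str, str], float]] = None,
    config: RegionConfig = RegionConfig(),
    seed: int = 0,
    gene_length: int = 600,
) -> list[TransporterAnnotation]:
    """Place transporter genes around BGCs with controlled densities.

    Per complete BGC, per region and family, each 1 kb window receives a
    Poisson number of genes with mean ``density_per_kb * width_kb``
    multiplied by ``factors[(family, region)]`` (default 1.0), so a
    uniform null uses no factors and an enriched fixture sets e.g.
    ``{("3.A.1", "in_cluster"): 5.0}``.  Deterministic per seed.
    """
    from .transporter_context import window_spans

    factors = dict(factors or {})
    rng = np.random.default_rng(seed)
    out: list[TransporterAnnotation] = []
    gi = 0
    for bgc in records:
        if bgc.contig_edge:
            continue
        for region, span in region_spans(bgc, config).items():
            for ws, we in window_spans(span, config.window):
                width_kb = (we - ws) / 1000.0
                for fam in families:
                    lam = density_per_kb * width_kb * factors.get((fam, region), 1.0)
                    for _ in range(rng.poisson(lam)):
                        start = int(ws + rng.integers(max(we - ws, 1)))
                        out.append(
                            TransporterAnnotation(
                                gene_id=f"tgene_{gi}",
                                contig_id=bgc.contig_id,
                                start=start,
                                end=start + gene_length,
                                tcdb_family=fam,
                                tcdb_superfamily=fam.rsplit(".", 1)[0],
                            )
                        )
                        gi += 1
    return out
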