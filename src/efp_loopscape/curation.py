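"""Ortholog-set construction for EF-P.

The curated EF-P set is built in three steps, mirroring how the family is
assembled from whole-proteome domain scans:

1. architecture filtering — keep proteins whose significant domain content is
   *exactly* {EFP_N, EFP, Elong-fact-P_C} (the KOW-like N-domain, the OB
   domain, and the C-terminal domain), at an E-value cutoff of 0.001;
2. paralog exclusion — drop records annotated as YeiP, the EF-P paralog that
   shares the same three-domain architecture;
3. enzyme repertoire detection — flag, per genome, the single-domain
   modification enzymes EpmA (tRNA-synt_2 domain), EpmC, EarP, and the
   deoxyhypusine-synthase-like family (DS domain).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "GenomeAnnotation",
    "EFP_ARCHITECTURE",
    "DEFAULT_EVALUE_CUTOFF",
    "read_fasta",
    "write_fasta",
    "read_domain_hits",
    "write_hits_tsv",
    "write_domtblout",
    "read_annotations",
    "filter_efp_candidates",
    "exclude_yeip",
    "detect_enzyme_repertoire",
    "curate",
]

EFP_ARCHITECTURE = frozenset({"EFP_N", "EFP", "Elong-fact-P_C"})
DEFAULT_EVALUE_CUTOFF = 1e-3

_ENZYME_DOMAINS = {"epmA": "tRNA-synt_2", "epmC": "EpmC", "earP": "EarP", "dhs": "DS"}

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with its genome of origin and free-text annotation."""

    protein_id: str
    genome_id: str
    sequence: str
    product_annotation: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID_AA
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class DomainHit:
    """One domain match on one protein (the unit of architecture filtering)."""

    protein_id: str
    domain_name: str
    evalue: float
    envelope: Optional[tuple] = None  # (start, end), 1-based inclusive

    def __post_init__(self):
        if self.evalue <= 0:
            raise ValueError(f"{self.protein_id}/{self.domain_name}: evalue must be > 0")
        if self.envelope is not None:
            start, end = self.envelope
            if not 1 <= start <= end:
                raise ValueError(f"{self.protein_id}/{self.domain_name}: bad envelope")


@dataclass
class GenomeAnnotation:
    """Per-genome modification-enzyme repertoire and EF-P copy number."""

    genome_id: str
    epmA: bool = False
    epmC: bool = False
    earP: bool = False
    dhs: bool = False
    efp_count: int = 0


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> list:
    """Read protein records from FASTA.

    The description line is parsed as ``>protein_id genome=G product`` when a
    ``genome=`` token is present; otherwise genome_id is empty and the whole
    remainder is the product annotation.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        genome = ""
        m = re.search(r"genome=(\S+)", desc)
        if m:
            genome = m.group(1)
            desc = (desc[: m.start()] + desc[m.end():]).strip()
        records.append(
            ProteinRecord(protein_id=rec.id, genome_id=genome, sequence=str(rec.seq).upper(), product_annotation=desc)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.protein_id,
            description=f"genome={r.genome_id} {r.product_annotation}".strip(),
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_domain_hits(path, dialect: str = "simple_tsv") -> list:
    """Read domain hits from a simple TSV or an hmmscan ``--domtblout`` file.

    simple_tsv columns: target_name (domain), query_name (protein), evalue,
    domain_name — with either a header row or ``domain_name`` omitted (three
    columns). hmmer_domtblout follows the whitespace-delimited HMMER3 layout:
    column 1 = domain name, column 4 = protein, column 13 = per-domain
    independent E-value, columns 20/21 = envelope coordinates.
    """
    hits = []
    if dialect == "simple_tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] in ("target_name", "domain_name"):
                    continue
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
                domain, protein, ev = parts[0], parts[1], parts[2]
                try:
                    evalue = float(ev)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad E-value {ev!r}") from exc
                envelope = None
                if len(parts) >= 5 and parts[3] and parts[4]:
                    try:
                        envelope = (int(parts[3]), int(parts[4]))
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: bad envelope") from exc
                hits.append(DomainHit(protein_id=protein, domain_name=domain, evalue=evalue, envelope=envelope))
    elif dialect == "hmmer_domtblout":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 21:
                    raise ParseError(f"{path}:{lineno}: expected >= 21 whitespace fields")
                try:
                    evalue = float(parts[12])  # per-domain independent E-value
                    envelope = (int(parts[19]), int(parts[20]))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
                hits.append(
                    DomainHit(protein_id=parts[3], domain_name=parts[0], evalue=evalue, envelope=envelope)
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return hits


def write_hits_tsv(hits: Iterable[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("target_name\tquery_name\tevalue\tenv_from\tenv_to\n")
        for h in hits:
            start, end = h.envelope if h.envelope else ("", "")
            fh.write(f"{h.domain_name}\t{h.protein_id}\t{h.evalue:.17g}\t{start}\t{end}\n")


def write_domtblout(hits: Iterable[DomainHit], path) -> None:
    """Write hits in the HMMER3 ``--domtblout`` column layout."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n")
        fh.write("#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------\n")
        for h in hits:
            start, end = h.envelope if h.envelope else (1, 1)
            fh.write(
                f"{h.domain_name:<20} -          100 {h.protein_id:<20} -          200 "
                f"{h.evalue:.17g}  100.0   0.0   1   1 {h.evalue:.17g} {h.evalue:.17g}  100.0   0.0 "
                f"{start:>5} {end:>5} {start:>5} {end:>5} {start:>5} {end:>5} 0.99 -\n"
            )


def read_annotations(path) -> pd.DataFrame:
    """Read a genome annotation TSV (genome_id, protein_id, product, flags)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "protein_id": str})
    for col in ("epmA", "epmC", "earP", "dhs"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df


# ---------------------------------------------------------------------------
# curation operations


def _significant_domain_sets(hits, evalue_cutoff: float) -> dict:
    """Map protein_id -> set of domain types with E-value <= cutoff."""
    domains: dict = {}
    for h in hits:
        if h.evalue <= evalue_cutoff:
            domains.setdefault(h.protein_id, set()).add(h.domain_name)
    return domains


def filter_efp_candidates(
    hits: list, records: Iterable[ProteinRecord], evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> list:
    """Keep proteins that exclusively contain the three EF-P domains.

    A protein passes iff its set of domain *types* with E-value <= cutoff
    equals {EFP_N, EFP, Elong-fact-P_C} — no missing and no extra significant
    domain. Repeated hits of one domain type collapse to the type. Output
    order follows the input record order.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    domains = _significant_domain_sets(hits, evalue_cutoff)
    return [r for r in records if domains.get(r.protein_id, set()) == EFP_ARCHITECTURE]


_YEIP_RE = re.compile(r"\byeip\b|elongation factor p-like", re.IGNORECASE)


def exclude_yeip(candidates: Iterable[ProteinRecord]):
    """Remove YeiP-annotated paralogs; also report per-genome EF-P counts.

    Returns ``(kept_records, counts)`` where counts is a DataFrame with
    columns genome_id, efp_count over genomes retaining >= 1 EF-P.
    """
    kept = [r for r in candidates if not _YEIP_RE.search(r.product_annotation or "")]
    counts = (
        pd.Series([r.genome_id for r in kept], dtype=str)
        .value_counts()
        .rename_axis("genome_id")
        .reset_index(name="efp_count")
        .sort_values("genome_id", kind="stable")
        .reset_index(drop=True)
    )
    return kept, counts


def detect_enzyme_repertoire(
    hits: list, records: Iterable[ProteinRecord], evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    efp_counts: pd.DataFrame = None,
) -> pd.DataFrame:
    """Flag per-genome modification enzymes from single-domain proteins.

    A genome is flagged epmA/epmC/earP/dhs iff some protein of that genome
    has exactly one significant domain type and it is tRNA-synt_2 / EpmC /
    EarP / DS respectively. ``efp_counts`` (from :func:`exclude_yeip`) fills
    the efp_count column; genomes absent from it get 0.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    records = list(records)
    domains = _significant_domain_sets(hits, evalue_cutoff)
    genome_of = {r.protein_id: r.genome_id for r in records}
    flags: dict = {}
    for r in records:
        flags.setdefault(r.genome_id, {k: False for k in _ENZYME_DOMAINS})
    for pid, doms in domains.items():
        if len(doms) != 1 or pid not in genome_of:
            continue
        (dom,) = doms
        for flag, name in _ENZYME_DOMAINS.items():
            if dom == name:
                flags[genome_of[pid]][flag] = True
    count_map = {}
    if efp_counts is not None and len(efp_counts):
        count_map = dict(zip(efp_counts["genome_id"], efp_counts["efp_count"]))
    rows = [
        {"genome_id": g, **{k: bool(v) for k, v in f.items()}, "efp_count": int(count_map.get(g, 0))}
        for g, f in sorted(flags.items())
    ]
    return pd.DataFrame(rows, columns=["genome_id", "epmA", "epmC", "earP", "dhs", "efp_count"])


def curate(
    hits: list,
    records: Iterable[ProteinRecord],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
):
    """Run the full curation: architecture filter, YeiP exclusion, enzymes.

    Returns ``(curated_records, paralog_counts, genome_annotations, stage_counts)``.
    """
    records = list(records)
    candidates = filter_efp_candidates(hits, records, evalue_cutoff)
    kept, counts = exclude_yeip(candidates)
    annotations = detect_enzyme_repertoire(hits, records, evalue_cutoff, efp_counts=counts)
    stage_counts = {
        "input_records": len(records),
        "architecture_pass": len(candidates),
        "yeip_excluded": len(candidates) - len(kept),
        "curated": len(kept),
        "multi_copy_genomes": int((counts["efp_count"] > 1).sum()) if len(counts) else 0,
    }
    return kept, counts, annotations, stage_counts
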