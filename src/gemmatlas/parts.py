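"""Promoter/5'UTR part extraction, Type IIS domestication and L0 emission.

The collection-design procedure turns an annotated genome into standardized
Golden Gate (Loop assembly) L0 parts:

* extract the putative promoter — a fixed-length window (default 1,800 bp)
  immediately upstream of the annotated TSS — and the entire 5'UTR;
* apply the splitting rules: 5'UTRs shorter than 500 bp are fused with the
  promoter into a single ``PROM5`` part, 5'UTRs of 500–3,000 bp give separate
  ``PROM`` and ``5UTR`` parts, and longer 5'UTRs exclude the gene;
* exclude genes whose promoter carries a run of ambiguous bases (>= 2
  consecutive N) within the 1,000 bp nearest the TSS;
* domesticate each part by minimal single-base substitutions until neither
  strand carries a BsaI (GGTCTC) or SapI (GCTCTTC) recognition site;
* flank each part with its fusion sites and outward-cutting BsaI handles.

All genomic coordinates are 1-based inclusive (GFF3 convention); minus-strand
parts are emitted reverse-complemented, i.e. in part orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ENZYMES",
    "DEFAULT_SYNTAX",
    "DesignRules",
    "GeneModel",
    "PromoterPart",
    "Exclusion",
    "L0Record",
    "SiteHit",
    "DomesticationError",
    "load_genome",
    "load_annotation",
    "gene_model",
    "extract_parts",
    "scan_sites",
    "domesticate",
    "build_l0",
    "strip_flanks",
    "simulate_assembly",
    "annotation_stats",
    "design_parts",
    "write_parts_fasta",
]

ENZYMES: dict[str, str] = {"BsaI": "GGTCTC", "SapI": "GCTCTTC"}

# Fusion-site syntax for promoter-class parts (common plant Type IIS syntax):
# PROM5 spans promoter+5'UTR and fuses straight into the CDS overhang.
DEFAULT_SYNTAX: dict[str, tuple[str, str]] = {
    "PROM5": ("GGAG", "AATG"),
    "PROM": ("GGAG", "TACT"),
    "5UTR": ("TACT", "AATG"),
}

_HANDLE5 = "GGTCTCA"  # BsaI site + 1-base spacer, cutting rightward into the fusion site
_HANDLE3 = "TGAGACC"  # mirror handle on the 3' side (BsaI on the minus strand)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DesignRules:
    """Extraction and exclusion thresholds, all lengths in bp."""

    upstream_len: int = 1800
    utr_split: int = 500
    utr_max: int = 3000
    n_scan_window: int = 1000
    n_run_min: int = 2
    enzymes: tuple[tuple[str, str], ...] = tuple(ENZYMES.items())

    def __post_init__(self) -> None:
        for name in ("upstream_len", "utr_split", "utr_max", "n_scan_window", "n_run_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.utr_split >= self.utr_max:
            raise ValueError("utr_split must be smaller than utr_max")


@dataclass(frozen=True)
class GeneModel:
    """Annotation anchors of one gene's primary transcript (1-based inclusive)."""

    gene_id: str
    seqid: str
    strand: str
    gene_start: int
    gene_end: int
    tss: int
    translation_start: int
    transcript_id: str

    @property
    def utr_length(self) -> int:
        """5'UTR length: TSS to the base before the translation start."""
        if self.strand == "+":
            return self.translation_start - self.tss
        return self.tss - self.translation_start


@dataclass
class PromoterPart:
    """An emitted part in part orientation with its genomic provenance."""

    part_type: str  # PROM5 | PROM | 5UTR
    gene_id: str
    sequence: str
    seqid: str
    start: int  # plus-strand coordinates of the source slice, 1-based inclusive
    end: int
    strand: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    truncated: bool = False


@dataclass(frozen=True)
class Exclusion:
    """A gene omitted from the collection, with a machine-readable reason."""

    gene_id: str
    reason: str  # utr_too_long | n_run_in_promoter
    detail: str = ""


@dataclass
class L0Record:
    """A flanked L0 part ready for Type IIS assembly bookkeeping."""

    name: str
    part_type: str
    sequence: str  # handle + fusion5 + part + fusion3 + handle
    fusion5: str
    fusion3: str
    part: PromoterPart | None = None


@dataclass(frozen=True)
class SiteHit:
    enzyme: str
    position: int  # 1-based start of the recognition footprint on the plus strand
    strand: str


class DomesticationError(ValueError):
    """Raised when a recognition site cannot be removed by any single-base edit."""


def load_genome(path) -> dict[str, str]:
    """Read a FASTA file into {sequence id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_annotation(path) -> gffutils.FeatureDB:
    """Load a GFF3 file into an in-memory gffutils database."""
    return gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )


def gene_model(db: gffutils.FeatureDB, gene_id: str) -> GeneModel:
    """Anchors of the gene's primary transcript (lowest mRNA id)."""
    gene = db[gene_id]
    mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
    if not mrnas:
        raise ValueError(f"gene {gene_id} has no mRNA feature")
    mrna = mrnas[0]
    cds = list(db.children(mrna, featuretype="CDS"))
    if not cds:
        raise ValueError(f"transcript {mrna.id} has no CDS feature")
    if gene.strand == "+":
        tss = mrna.start
        translation_start = min(c.start for c in cds)
    elif gene.strand == "-":
        tss = mrna.end
        translation_start = max(c.end for c in cds)
    else:
        raise ValueError(f"gene {gene_id} has no strand")
    if (gene.strand == "+" and translation_start <= tss) or (
        gene.strand == "-" and translation_start >= tss
    ):
        raise ValueError(f"gene {gene_id}: TSS is not upstream of the translation start")
    return GeneModel(
        gene_id, gene.seqid, gene.strand, gene.start, gene.end, tss,
        translation_start, mrna.id,
    )


def _slice(seq: str, start: int, end: int, strand: str) -> str:
    """1-based inclusive slice, reverse-complemented for minus-strand parts."""
    s = seq[start - 1 : end]
    return _revcomp(s) if strand == "-" else s


def _has_n_run(window: str, n_run_min: int) -> bool:
    return "N" * n_run_min in window


def extract_parts(
    genome: dict[str, str],
    db: gffutils.FeatureDB,
    gene_id: str,
    rules: DesignRules | None = None,
) -> list[PromoterPart] | Exclusion:
    """Apply the extraction and exclusion rules to one gene.

    Returns a single fused ``PROM5`` part, a ``PROM`` + ``5UTR`` pair, or an
    :class:`Exclusion`.  Upstream windows running off the sequence start/end
    are truncated with a warning.  Sequences are raw (pre-domestication).
    """
    rules = rules or DesignRules()
    model = gene_model(db, gene_id)
    seq = genome[model.seqid]
    utr_len = model.utr_length
    if utr_len > rules.utr_max:
        return Exclusion(gene_id, "utr_too_long", f"5'UTR of {utr_len} bp exceeds {rules.utr_max}")

    if model.strand == "+":
        prom_lo, prom_hi = model.tss - rules.upstream_len, model.tss - 1
        utr_lo, utr_hi = model.tss, model.translation_start - 1
    else:
        prom_lo, prom_hi = model.tss + 1, model.tss + rules.upstream_len
        utr_lo, utr_hi = model.translation_start + 1, model.tss
    truncated = False
    if prom_lo < 1:
        warnings.warn(f"{gene_id}: upstream window truncated at sequence start", stacklevel=2)
        prom_lo, truncated = 1, True
    if prom_hi > len(seq):
        warnings.warn(f"{gene_id}: upstream window truncated at sequence end", stacklevel=2)
        prom_hi, truncated = len(seq), True

    prom_seq = _slice(seq, prom_lo, prom_hi, model.strand)
    # promoter-proximal window: the bases nearest the TSS, i.e. the tail of
    # the promoter in part orientation
    window = prom_seq[-rules.n_scan_window :]
    if _has_n_run(window, rules.n_run_min):
        return Exclusion(
            gene_id, "n_run_in_promoter",
            f">= {rules.n_run_min} consecutive N within {rules.n_scan_window} bp of the TSS",
        )

    def part(ptype: str, lo: int, hi: int) -> PromoterPart:
        return PromoterPart(
            ptype, gene_id, _slice(seq, lo, hi, model.strand), model.seqid,
            lo, hi, model.strand, truncated=truncated and ptype != "5UTR",
        )

    if utr_len < rules.utr_split:
        if model.strand == "+":
            return [part("PROM5", prom_lo, utr_hi)]
        return [part("PROM5", utr_lo, prom_hi)]
    return [part("PROM", prom_lo, prom_hi), part("5UTR", utr_lo, utr_hi)]


def scan_sites(
    sequence: str, enzymes: dict[str, str] | None = None
) -> list[SiteHit]:
    """All recognition-site occurrences on both strands, overlaps included.

    Positions are the 1-based start of the footprint on the given (plus)
    strand; minus-strand hits are occurrences of the reverse complement.
    """
    enzymes = enzymes or ENZYMES
    sequence = sequence.upper()
    if set(sequence) - set("ACGTN"):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    hits: list[SiteHit] = []
    for name, site in enzymes.items():
        for strand, pattern in (("+", site), ("-", _revcomp(site))):
            start = sequence.find(pattern)
            while start != -1:
                hits.append(SiteHit(name, start + 1, strand))
                start = sequence.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.position, h.strand, h.enzyme))
    return hits


def _substitution_offsets(m: int) -> list[int]:
    """Candidate offsets within an m-long footprint: 3rd base first, then outward."""
    return sorted(range(m), key=lambda i: (abs(i - 2), i))


def domesticate(
    sequence: str, enzymes: dict[str, str] | None = None
) -> tuple[str, list[tuple[int, str, str]]]:
    """Remove every recognition site by deterministic single-base substitutions.

    Sites are processed left to right.  For each site the 3rd footprint base
    is mutated first, preferring a transition; if a candidate substitution
    fails to clear the site or creates a new one, the remaining footprint
    bases are tried in a fixed outward order.  Raises
    :class:`DomesticationError` when no single-base edit clears a site.
    """
    enzymes = enzymes or ENZYMES
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must contain only A, C, G, T")
    site_len = {name: len(site) for name, site in enzymes.items()}
    edits: list[tuple[int, str, str]] = []
    max_rounds = 3 * len(scan_sites(seq, enzymes)) + 1
    for _ in range(max_rounds):
        hits = scan_sites(seq, enzymes)
        if not hits:
            return seq, edits
        hit = hits[0]
        m = site_len[hit.enzyme]
        old_hits = set(hits)
        placed = False
        for offset in _substitution_offsets(m):
            idx = hit.position - 1 + offset
            base = seq[idx]
            candidates = [_TRANSITION[base]] + sorted(set("ACGT") - {base, _TRANSITION[base]})
            for new_base in candidates:
                trial = seq[:idx] + new_base + seq[idx + 1 :]
                new_hits = set(scan_sites(trial, enzymes))
                if hit not in new_hits and new_hits <= old_hits:
                    edits.append((idx + 1, base, new_base))
                    seq = trial
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise DomesticationError(
                f"unresolvable {hit.enzyme} site at position {hit.position}: "
                "every single-base substitution leaves or creates a site"
            )
    raise DomesticationError("domestication did not converge within the edit budget")


def build_l0(
    part: PromoterPart, syntax: dict[str, tuple[str, str]] | None = None
) -> L0Record:
    """Flank a domesticated part with its fusion sites and BsaI handles."""
    syntax = syntax or DEFAULT_SYNTAX
    if part.part_type not in syntax:
        raise ValueError(f"no fusion-site pair configured for part type {part.part_type!r}")
    if scan_sites(part.sequence):
        raise ValueError(f"part {part.gene_id}/{part.part_type} still carries enzyme sites")
    f5, f3 = syntax[part.part_type]
    seq = _HANDLE5 + f5 + part.sequence + f3 + _HANDLE3
    return L0Record(f"{part.gene_id}_{part.part_type}", part.part_type, seq, f5, f3, part)


def strip_flanks(record: L0Record) -> str:
    """Inverse of :func:`build_l0`: recover the bare domesticated part."""
    lo = len(_HANDLE5) + len(record.fusion5)
    hi = len(record.sequence) - len(_HANDLE3) - len(record.fusion3)
    return record.sequence[lo:hi]


@dataclass(frozen=True)
class Acceptor:
    """Assembly acceptor: expected first/last overhangs plus backbone length."""

    fusion_first: str
    fusion_last: str
    backbone: str = ""


def simulate_assembly(acceptor: Acceptor, parts: list[L0Record]) -> dict:
    """Check that the parts' overhangs form a unique closed chain and ligate.

    On success returns ``{"success": True, "sequence": ..., "length": ...}``
    where the circular sequence is backbone + fusion/part chain with each
    fusion site counted once per junction.  On failure the report lists
    duplicated and unmatched overhangs and any internal enzyme sites.
    """
    errors: list[str] = []
    for rec in parts:
        core = strip_flanks(rec)
        if scan_sites(core):
            errors.append(f"internal enzyme site in part {rec.name}")
    f5s = [rec.fusion5 for rec in parts]
    dup = sorted({f for f in f5s if f5s.count(f) > 1})
    for f in dup:
        errors.append(f"duplicate overhang {f}")
    if errors:
        return {"success": False, "errors": errors}

    by_f5 = {rec.fusion5: rec for rec in parts}
    chain: list[L0Record] = []
    cur = acceptor.fusion_first
    for _ in range(len(parts)):
        nxt = by_f5.get(cur)
        if nxt is None:
            return {"success": False, "errors": [f"unmatched overhang {cur}"]}
        chain.append(nxt)
        cur = nxt.fusion3
    if cur != acceptor.fusion_last or len(chain) != len(parts):
        return {"success": False, "errors": [f"chain does not terminate at {acceptor.fusion_last}"]}

    insert = "".join(rec.fusion5 + strip_flanks(rec) for rec in chain) + acceptor.fusion_last
    sequence = acceptor.backbone + insert
    return {
        "success": True,
        "sequence": sequence,
        "length": len(sequence),
        "order": [rec.name for rec in chain],
    }


def annotation_stats(db: gffutils.FeatureDB) -> dict:
    """Median and distribution of 5'UTR and intergenic lengths.

    5'UTR length is summed over the ``five_prime_UTR`` intervals of each
    gene's primary transcript; intergenic lengths are the gaps between
    consecutive gene spans per sequence, with overlaps recorded as 0.
    """
    utr_rows = []
    genes = list(db.features_of_type("gene"))
    if not genes:
        raise ValueError("annotation contains no gene features")
    for gene in genes:
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        if not mrnas:
            continue
        utrs = list(db.children(mrnas[0], featuretype="five_prime_UTR"))
        length = sum(u.end - u.start + 1 for u in utrs)
        utr_rows.append({"gene_id": gene.id, "utr_length": length})
    utr_df = pd.DataFrame(utr_rows)

    inter_rows = []
    by_seq: dict[str, list] = {}
    for gene in genes:
        by_seq.setdefault(gene.seqid, []).append(gene)
    for seqid, gs in by_seq.items():
        gs = sorted(gs, key=lambda g: (g.start, g.end))
        for a, b in zip(gs, gs[1:]):
            gap = max(b.start - a.end - 1, 0)
            inter_rows.append({"seqid": seqid, "left": a.id, "right": b.id, "length": gap})
    inter_df = pd.DataFrame(inter_rows)

    return {
        "utr_lengths": utr_df,
        "intergenic_lengths": inter_df,
        "median_utr": float(utr_df["utr_length"].median()) if len(utr_df) else float("nan"),
        "median_intergenic": float(inter_df["length"].median()) if len(inter_df) else float("nan"),
    }


def design_parts(
    genome: dict[str, str],
    db: gffutils.FeatureDB,
    gene_ids: list[str],
    rules: DesignRules | None = None,
    syntax: dict[str, tuple[str, str]] | None = None,
) -> tuple[list[L0Record], list[Exclusion]]:
    """Extraction -> domestication -> L0 emission over a gene list."""
    rules = rules or DesignRules()
    records: list[L0Record] = []
    exclusions: list[Exclusion] = []
    for gid in gene_ids:
        result = extract_parts(genome, db, gid, rules)
        if isinstance(result, Exclusion):
            exclusions.append(result)
            continue
        for part in result:
            domseq, edits = domesticate(part.sequence, dict(rules.enzymes))
            records.append(build_l0(replace(part, sequence=domseq, edits=edits), syntax))
    return records, exclusions


def write_parts_fasta(records: list[L0Record], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name} type={rec.part_type} fusion={rec.fusion5}-{rec.fusion3}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")
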