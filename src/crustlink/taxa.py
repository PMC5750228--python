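"""Marker-gene taxon profiling and isolate matching.

Community structure is read out of shotgun metagenomes through
single-copy ribosomal-protein marker genes (e.g. rplO, the 50S L15
gene): the family with the widest community coverage is selected,
per-sample assembled-gene counts become relative abundances, and
exometabolite-profiled isolates are linked to environmental taxa by
global marker-sequence identity. A lightweight fragment-identity routine
approximates genome-level average nucleotide identity for synthetic
genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import edlib
import numpy as np
import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

LINEAGE_RANKS = ("p", "c", "o", "f", "g")


def select_marker_family(family_gene_counts: Mapping[str, int]) -> str:
    """Pick the marker family with the most assembled genes overall.

    ``family_gene_counts`` maps family label (e.g. "rplO") to the total
    number of assembled marker genes across the data set; ties break
    alphabetically (logged).
    """
    if not family_gene_counts:
        raise ValueError("empty marker catalog")
    best = max(family_gene_counts.values())
    winners = sorted(f for f, n in family_gene_counts.items() if n == best)
    if len(winners) > 1:
        logger.info("select_marker_family: tie between %s; choosing %s",
                    winners, winners[0])
    return winners[0]


def catalog_gene_counts(catalog: Mapping[str, pd.DataFrame]) -> dict[str, int]:
    """Total assembled genes per family for a {family: gene x sample
    count table} catalog."""
    return {fam: int(df.shape[0]) for fam, df in catalog.items()}


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )


def global_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity from a Needleman–Wunsch global alignment.

    Identity = identical columns / alignment length (gap columns
    included in the denominator) x 100. Among co-optimal alignments the
    first reported one is used; the argument pair is canonically ordered
    first so the result is symmetric by construction.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aln = _aligner(match, mismatch, gap).align(seq_a, seq_b)[0]
    c = aln.counts()
    length = c.identities + c.mismatches + c.gaps
    return 100.0 * c.identities / length


@dataclass(frozen=True)
class MatchResult:
    isolate_id: str
    taxon_id: str
    percent_identity: float
    is_best: bool


def best_match(
    isolate_id: str,
    isolate_seq: str,
    env_markers: Mapping[str, str],
    **scoring,
) -> pd.DataFrame:
    """Rank environmental marker genes by identity to an isolate marker.

    The highest percent identity wins ("closest matching environmental
    relative"); ties break by taxon label. Returns the full ranked list
    with an ``is_best`` flag on exactly one row.
    """
    if not env_markers:
        raise ValueError("no environmental markers to match against")
    rows = [
        (isolate_id, taxon, global_identity(isolate_seq, seq, **scoring))
        for taxon, seq in env_markers.items()
    ]
    df = pd.DataFrame(rows, columns=["isolate_id", "taxon_id", "percent_identity"])
    df = df.sort_values(
        ["percent_identity", "taxon_id"], ascending=[False, True]
    ).reset_index(drop=True)
    ties = df["percent_identity"] == df.loc[0, "percent_identity"]
    if ties.sum() > 1:
        logger.info("best_match: %s ties at %.2f%% among %s; choosing %s",
                    isolate_id, df.loc[0, "percent_identity"],
                    list(df.loc[ties, "taxon_id"]), df.loc[0, "taxon_id"])
    df["is_best"] = False
    df.loc[0, "is_best"] = True
    return df


def match_isolates(
    isolate_markers: Mapping[str, str],
    env_markers: Mapping[str, str],
    **scoring,
) -> pd.DataFrame:
    """Best-match every isolate marker; concatenated ranked lists."""
    return pd.concat(
        [best_match(iso, seq, env_markers, **scoring)
         for iso, seq in isolate_markers.items()],
        ignore_index=True,
    )


@dataclass
class FragmentIdentityResult:
    """Outcome of fragment-based genome comparison."""

    mean_identity: float | None
    n_fragments: int
    identities: list[float]

    @property
    def ok(self) -> bool:
        return self.n_fragments > 0


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment_length) from an extended cigar (=XID ops)."""
    matches = length = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            length += n
            if ch == "=":
                matches += n
    return matches, length


def fragment_identity(
    genome_a: str,
    genome_b: str,
    fragment_length: int = 1020,
    kmer: int = 16,
    min_coverage: float = 0.7,
    min_identity: float = 30.0,
) -> FragmentIdentityResult:
    """Mean identity of genome_a fragments against genome_b.

    genome_a is cut into non-overlapping fragments of
    ``fragment_length``; each fragment is anchored in genome_b by exact
    shared k-mers (majority diagonal) and globally aligned to the
    corresponding window with a banded edit-distance aligner. Fragments
    without a k-mer anchor, with a target window shorter than
    ``min_coverage`` of the fragment, or below ``min_identity`` percent
    are dropped. With no surviving fragments the result is flagged
    undefined (``ok`` is False).
    """
    if len(genome_a) < fragment_length:
        raise ValueError("genome_a shorter than one fragment")
    index: dict[str, list[int]] = {}
    for i in range(0, len(genome_b) - kmer + 1):
        index.setdefault(genome_b[i:i + kmer], []).append(i)

    identities: list[float] = []
    n_frag = len(genome_a) // fragment_length
    pad = max(32, fragment_length // 20)
    for f in range(n_frag):
        frag = genome_a[f * fragment_length:(f + 1) * fragment_length]
        diagonals: list[int] = []
        for i in range(0, fragment_length - kmer + 1, kmer // 2):
            for pos in index.get(frag[i:i + kmer], ()):
                diagonals.append(pos - i)
        if not diagonals:
            continue
        diag = int(np.median(diagonals))
        start = max(0, diag - pad)
        end = min(len(genome_b), diag + fragment_length + pad)
        window = genome_b[start:end]
        if len(window) < min_coverage * fragment_length:
            continue
        res = edlib.align(frag, window, mode="HW", task="path")
        matches, length = _cigar_stats(res["cigar"])
        ident = 100.0 * matches / length
        if ident < min_identity:
            continue
        identities.append(ident)
    if not identities:
        logger.info("fragment_identity: no surviving fragments")
        return FragmentIdentityResult(None, 0, [])
    return FragmentIdentityResult(
        float(np.mean(identities)), len(identities), identities
    )


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize a taxon x sample count matrix so columns sum to 1."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {list(zero.index)}")
    out = counts / sums
    return out.astype(float)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a "Name (p)/ Name (c)/ ..." lineage string to rank -> name."""
    out: dict[str, str] = {}
    for part in lineage.split("/"):
        part = part.strip()
        if not part:
            continue
        if not (part.endswith(")") and "(" in part):
            raise ValueError(f"malformed lineage segment {part!r}")
        name, _, rank = part.rpartition("(")
        rank = rank.rstrip(")").strip()
        if rank not in LINEAGE_RANKS:
            raise ValueError(f"unknown rank {rank!r} in {part!r}")
        out[rank] = name.strip()
    return out


def aggregate_taxonomy(
    abundances: pd.DataFrame,
    taxonomy: Mapping[str, str],
    rank: str = "p",
) -> pd.DataFrame:
    """Sum relative abundances within a taxonomic rank.

    Taxa without a lineage, or whose lineage lacks the requested rank,
    fall into an "unclassified" bucket; columns still sum to 1.
    """
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    groups: dict[str, str] = {}
    for taxon in abundances.index:
        lin = taxonomy.get(taxon)
        if lin is None:
            groups[taxon] = "unclassified"
            continue
        try:
            parsed = parse_lineage(lin)
        except ValueError as err:
            raise ValueError(f"taxon {taxon!r}: {err}") from err
        groups[taxon] = parsed.get(rank, "unclassified")
    return abundances.groupby(abundances.index.map(groups)).sum()
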