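"""16S rRNA gene detection and phylum-level classification.

Detection finds contig regions that share k-mers with a reference panel
of 16S sequences (a light-weight stand-in for a covariance-model search,
preserving the same pipeline contract: locate >=1,000-1,200 nt 16S
regions on either strand). Classification is a naive-Bayes word
classifier with bootstrap confidence, the standard design for
phylum-level 16S assignment: the winning phylum maximizes the sum of log
word likelihoods (add-half smoothing) over the query's distinct 8-mers,
and confidence is the percentage of word-subsample bootstraps that agree
with the full-set winner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SsuHit", "SsuClassification", "detect_ssu", "classify_ssu",
    "dedupe_identical", "NaiveBayesSsuClassifier",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SsuHit:
    sag_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SsuClassification:
    hit: SsuHit | None
    phylum: str
    confidence: float   # bootstrap support, 0-100


def _kmer_positions(seq: str, panel_kmers: set[str], k: int) -> np.ndarray:
    """Boolean array: does the k-mer starting at each position match?"""
    n = len(seq) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    return np.fromiter(
        (seq[i : i + k] in panel_kmers for i in range(n)),
        dtype=bool, count=n,
    )


def detect_ssu(
    contigs: dict[str, str],
    ref_panel: list[str] | dict[str, str],
    min_len: int = 1000,
    sag_id: str = "",
    k: int = 16,
    window: int = 200,
    threshold: float = 0.35,
    merge_gap: int = 300,
) -> list[SsuHit]:
    """Locate putative 16S regions by shared-k-mer density.

    A sliding window (length ``window``) passes where the fraction of its
    k-mer starts found in the panel is >= ``threshold``; passing windows
    are merged within ``merge_gap``, each merged region is trimmed to its
    outermost matching k-mers, and regions shorter than ``min_len`` are
    dropped. Both strands are searched; for minus-strand hits the
    reported sequence is the reverse complement of the contig slice.
    """
    if min_len < 0:
        raise ValueError("min_len must be nonnegative")
    if not ref_panel:
        raise ValueError("empty 16S reference panel")
    seqs = list(ref_panel.values()) if isinstance(ref_panel, dict) else list(ref_panel)
    fwd_kmers: set[str] = set()
    for s in seqs:
        fwd_kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    rev_kmers = {_revcomp(w) for w in fwd_kmers}
    hits: list[SsuHit] = []
    for cid, contig in contigs.items():
        for strand, panel in (("+", fwd_kmers), ("-", rev_kmers)):
            match = _kmer_positions(contig, panel, k)
            if match.size == 0 or not match.any():
                continue
            # windowed match density at each window start
            c = np.concatenate(([0], np.cumsum(match)))
            w = min(window, match.size)
            dens = (c[w:] - c[:-w]) / w
            ok = np.flatnonzero(dens >= threshold)
            if ok.size == 0:
                continue
            # merge passing window starts within merge_gap
            breaks = np.flatnonzero(np.diff(ok) > merge_gap)
            groups = np.split(ok, breaks + 1)
            for g in groups:
                lo, hi = int(g[0]), int(g[-1]) + w  # candidate span
                span = np.flatnonzero(match[lo:hi])
                if span.size == 0:
                    continue
                start = lo + int(span[0])
                end = lo + int(span[-1]) + k
                if end - start < min_len:
                    continue
                piece = contig[start:end]
                if strand == "-":
                    piece = _revcomp(piece)
                hits.append(SsuHit(sag_id, cid, start, end, strand, piece))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def dedupe_identical(seqs: list[str]) -> list[str]:
    """Drop exact duplicate sequences, keeping first occurrences in order."""
    seen: set[str] = set()
    out = []
    for s in seqs:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


class NaiveBayesSsuClassifier:
    """Word-based naive-Bayes phylum classifier over a labeled 16S refdb.

    ``refdb`` maps reference id -> (phylum, sequence). The likelihood of a
    word under a phylum is (number of that phylum's references containing
    the word + 0.5) / (number of references + 1).
    """

    def __init__(self, refdb: dict[str, tuple[str, str]], k: int = 8):
        if not refdb:
            raise ValueError("empty reference database")
        self.k = k
        self.phyla = sorted({ph for ph, _ in refdb.values()})
        if len(self.phyla) < 2:
            raise ValueError("refdb must contain at least 2 phyla")
        words: set[str] = set()
        by_ph: dict[str, list[set[str]]] = {ph: [] for ph in self.phyla}
        for ph, seq in refdb.values():
            ws = {seq[i : i + k] for i in range(len(seq) - k + 1)}
            by_ph[ph].append(ws)
            words.update(ws)
        self.word_index = {w: i for i, w in enumerate(sorted(words))}
        W = len(self.word_index)
        self.loglik = np.zeros((len(self.phyla), W))
        self.log_missing = np.zeros(len(self.phyla))
        for pi, ph in enumerate(self.phyla):
            n = len(by_ph[ph])
            counts = np.zeros(W)
            for ws in by_ph[ph]:
                for w in ws:
                    counts[self.word_index[w]] += 1
            self.loglik[pi] = np.log((counts + 0.5) / (n + 1.0))
            self.log_missing[pi] = np.log(0.5 / (n + 1.0))

    def _query_matrix(self, seq: str) -> np.ndarray:
        """Per-phylum log-likelihood of each distinct query word."""
        k = self.k
        qwords = sorted({seq[i : i + k] for i in range(len(seq) - k + 1)})
        cols = np.empty((len(self.phyla), len(qwords)))
        for j, w in enumerate(qwords):
            i = self.word_index.get(w)
            cols[:, j] = self.loglik[:, i] if i is not None else self.log_missing
        return cols

    def classify(self, seq: str, n_boot: int = 100, seed: int = 0
                 ) -> tuple[str, float]:
        if len(seq) < self.k:
            raise ValueError("query shorter than word size")
        cols = self._query_matrix(seq)
        winner = int(np.argmax(cols.sum(axis=1)))
        W = cols.shape[1]
        m = -(-W // 8)  # ceil(W/8) words per bootstrap subsample
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, W, size=(n_boot, m))
        agree = 0
        for b in range(n_boot):
            agree += int(np.argmax(cols[:, idx[b]].sum(axis=1)) == winner)
        conf = 100.0 * agree / n_boot
        return self.phyla[winner], conf


def classify_ssu(
    seq: str,
    refdb: dict[str, tuple[str, str]],
    k: int = 8,
    n_boot: int = 100,
    seed: int = 0,
    hit: SsuHit | None = None,
) -> SsuClassification:
    """Classify one 16S sequence; see :class:`NaiveBayesSsuClassifier`."""
    clf = NaiveBayesSsuClassifier(refdb, k=k)
    phylum, conf = clf.classify(seq, n_boot=n_boot, seed=seed)
    return SsuClassification(hit=hit, phylum=phylum, confidence=conf)


def refdb_from_panel(
    phylum_refs: dict[str, str],
    n_variants: int = 3,
    divergence: float = 0.03,
    seed: int = 0,
) -> dict[str, tuple[str, str]]:
    """Expand a per-phylum reference panel into a small labeled refdb."""
    from .community import child_seed, evolve_ssu

    refdb: dict[str, tuple[str, str]] = {}
    for ph, ref in phylum_refs.items():
        refdb[f"{ph}|ref0"] = (ph, ref)
        for i in range(1, n_variants):
            v = evolve_ssu(ref, divergence, child_seed(seed, "refdb", ph, i))
            refdb[f"{ph}|ref{i}"] = (ph, v)
    return refdb
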