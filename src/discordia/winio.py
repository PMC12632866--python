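"""Alignment I/O, windowing and site filtering.

Coordinates are 0-based half-open throughout. Windows are fixed-size,
non-overlapping slices of a per-chromosome multiple alignment; a trailing
remainder shorter than the window size is discarded. Site filters follow the
emulated study design: windows overlapping repeat-masked sequence are
excluded, windows whose shortest ungapped per-taxon sequence is below 150 bp
are excluded, and SNP sites are kept only when bi-allelic among non-missing
calls with a missing fraction at or below 0.2 (with optional bp thinning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._phylo import parse_newick, read_newick_trees

__all__ = [
    "AlignmentWindow",
    "SnpMatrix",
    "make_windows",
    "filter_windows",
    "extract_biallelic_sites",
    "read_fasta",
    "write_fasta",
    "read_maf",
    "read_newick_trees",
    "parse_newick",
    "read_manifest",
    "write_manifest",
]

log = logging.getLogger(__name__)

MISSING = frozenset("Nn-?")


@dataclass
class AlignmentWindow:
    """A contiguous multi-taxon alignment slice with genome coordinates.

    ``repeat_flag`` may be a boolean or a masked fraction in [0, 1]; any
    truthy/positive value marks the window as repeat-overlapping.
    """

    sequences: dict[str, str]
    chrom: str = "chr1"
    start: int = 0
    end: int = 0
    repeat_flag: bool | float = False

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"ragged window {self.chrom}:{self.start}-{self.end}: "
                f"sequence lengths {sorted(lengths)}"
            )
        if self.sequences and self.end - self.start != next(iter(lengths)):
            raise ValueError(
                f"window span {self.end - self.start} != alignment length "
                f"{next(iter(lengths))}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def ungapped_lengths(self) -> dict[str, int]:
        """Per-taxon count of non-gap, non-missing residues."""
        out = {}
        for taxon, seq in self.sequences.items():
            out[taxon] = sum(1 for ch in seq if ch not in MISSING)
        return out


@dataclass
class SnpMatrix:
    """Haploid allele calls at retained variant sites.

    ``alleles`` has shape (n_taxa, n_sites) with single-character entries
    from {A, C, G, T, N}; N marks missing."""

    taxa: list[str]
    alleles: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype="S1")
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != len(self.taxa):
            raise ValueError("alleles must be (n_taxa, n_sites)")
        if self.alleles.shape[1] != len(self.pos) or len(self.pos) != len(self.chrom):
            raise ValueError("site annotation lengths disagree")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.alleles[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None


# ---------------------------------------------------------------------------
# Windowing and filters
# ---------------------------------------------------------------------------


def make_windows(
    alignment: dict[str, str],
    window_size: int = 10_000,
    chrom: str = "chr1",
    repeat_intervals: Optional[Sequence[tuple[int, int]]] = None,
) -> list[AlignmentWindow]:
    """Cut a per-chromosome alignment into consecutive non-overlapping
    windows of exactly ``window_size``; the trailing remainder is discarded.

    ``repeat_intervals`` (0-based half-open, chromosome coordinates) set each
    window's ``repeat_flag`` to the fraction of its span covered by masked
    sequence."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    L = lengths.pop()
    out = []
    for start in range(0, L - window_size + 1, window_size):
        end = start + window_size
        flag: bool | float = False
        if repeat_intervals:
            covered = 0
            for a, b in repeat_intervals:
                covered += max(0, min(b, end) - max(a, start))
            flag = covered / window_size
        out.append(
            AlignmentWindow(
                sequences={t: s[start:end] for t, s in alignment.items()},
                chrom=chrom,
                start=start,
                end=end,
                repeat_flag=flag,
            )
        )
    return out


def filter_windows(
    windows: Iterable[AlignmentWindow],
    min_len: int = 150,
    max_repeat_fraction: float = 0.0,
    length_policy: str = "per_taxon",
) -> list[AlignmentWindow]:
    """Apply the repeat and minimum-length window filters.

    A window is removed when its repeat flag/fraction exceeds
    ``max_repeat_fraction`` (default 0: any repeat overlap excludes), or when
    its ungapped non-missing length falls below ``min_len`` (a length of
    exactly ``min_len`` is retained). Under the default ``per_taxon`` policy
    the minimum over taxa of ungapped lengths is used; ``alignment`` uses the
    full alignment span instead.
    """
    if length_policy not in ("per_taxon", "alignment"):
        raise ValueError("length_policy must be 'per_taxon' or 'alignment'")
    kept = []
    for w in windows:
        frac = float(w.repeat_flag) if not isinstance(w.repeat_flag, bool) else (
            1.0 if w.repeat_flag else 0.0
        )
        if frac > max_repeat_fraction:
            continue
        if length_policy == "per_taxon":
            eff = min(w.ungapped_lengths().values(), default=0)
        else:
            eff = w.length
        if eff < min_len:
            continue
        kept.append(w)
    return kept


# ---------------------------------------------------------------------------
# SNP-site extraction
# ---------------------------------------------------------------------------


def extract_biallelic_sites(
    windows: Iterable[AlignmentWindow] | dict[str, str],
    outgroup: str,
    max_missing: float = 0.2,
    thin: int = 0,
) -> SnpMatrix:
    """Retain polymorphic bi-allelic sites.

    A site survives when, among non-missing calls, exactly two alleles
    segregate (monomorphic and 3+-allelic sites are dropped), and the
    fraction of missing calls over all taxa is <= ``max_missing``. With
    ``thin`` > 0 only sites at least ``thin`` bp apart are kept per
    chromosome, greedily left to right. Gaps count as missing.
    """
    if isinstance(windows, dict):
        windows = [
            AlignmentWindow(sequences=windows, end=len(next(iter(windows.values()))))
        ]
    windows = list(windows)
    if not windows:
        return SnpMatrix([], np.empty((0, 0), dtype="S1"), np.array([]), np.array([]))
    taxa = windows[0].taxa
    for w in windows:
        if w.taxa != taxa:
            raise ValueError("all windows must share an identical taxon set/order")
    if outgroup not in taxa:
        raise KeyError(f"outgroup {outgroup!r} not among taxa {taxa}")

    keep_alleles, keep_chrom, keep_pos = [], [], []
    for w in windows:
        if w.length == 0:
            continue
        arr = np.array(
            [np.frombuffer(w.sequences[t].upper().encode(), dtype="S1") for t in taxa]
        )
        missing = np.isin(arr, [b"N", b"-", b"?"])
        arr = np.where(missing, b"N", arr)
        miss_frac = missing.mean(axis=0)
        # distinct non-missing alleles per site
        n_distinct = np.zeros(arr.shape[1], dtype=int)
        for base in (b"A", b"C", b"G", b"T"):
            n_distinct += (arr == base).any(axis=0)
        ok = (n_distinct == 2) & (miss_frac <= max_missing)
        if ok.any():
            keep_alleles.append(arr[:, ok])
            idx = np.nonzero(ok)[0]
            keep_chrom.append(np.full(len(idx), w.chrom, dtype=object))
            keep_pos.append(w.start + idx)

    if not keep_alleles:
        return SnpMatrix(
            taxa, np.empty((len(taxa), 0), dtype="S1"), np.array([]), np.array([])
        )
    alleles = np.concatenate(keep_alleles, axis=1)
    chrom = np.concatenate(keep_chrom)
    pos = np.concatenate(keep_pos)
    order = np.lexsort((pos, chrom.astype(str)))
    alleles, chrom, pos = alleles[:, order], chrom[order], pos[order]

    if thin > 0:
        keep = np.zeros(len(pos), dtype=bool)
        last_chrom, last_pos = None, None
        for i in range(len(pos)):
            if chrom[i] != last_chrom or pos[i] - last_pos >= thin:
                keep[i] = True
                last_chrom, last_pos = chrom[i], pos[i]
        alleles, chrom, pos = alleles[:, keep], chrom[keep], pos[keep]

    return SnpMatrix(taxa, alleles, chrom, pos)


# ---------------------------------------------------------------------------
# FASTA / MAF / TSV
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        log.warning("empty FASTA file: %s", path)
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_maf(path: str | Path, reference: Optional[str] = None) -> dict[str, dict[str, str]]:
    """Read a MAF subset (a/s lines) and stitch blocks per reference chromosome.

    The reference taxon is the first ``s`` line of each block (or the taxon
    named by ``reference``). Alignment columns where the reference has a gap
    are dropped, so output coordinates are ungapped reference coordinates;
    reference positions not covered by any block are filled with ``N``.
    Returns chrom -> {taxon: sequence}.
    """
    blocks: list[list[tuple[str, str, int, int, str, int, str]]] = []
    current: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if current:
                    blocks.append(current)
                    current = []
                continue
            if line.startswith("#") or line.startswith("a"):
                if line.startswith("a") and current:
                    blocks.append(current)
                    current = []
                continue
            if line.startswith("s"):
                parts = line.split()
                if len(parts) != 7:
                    raise ValueError(f"line {lineno}: malformed MAF 's' line")
                _, src, start, size, strand, src_size, text = parts
                taxon, _, chrom = src.partition(".")
                if not chrom:
                    chrom = src
                try:
                    current.append(
                        (taxon, chrom, int(start), int(size), strand, int(src_size), text)
                    )
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: non-integer MAF field") from exc
            # other line types (i/e/q) are out of scope and ignored
    if current:
        blocks.append(current)
    if not blocks:
        log.warning("empty MAF file: %s", path)
        return {}

    chrom_sizes: dict[str, int] = {}
    taxa: list[str] = []
    for block in blocks:
        ref = block[0] if reference is None else next(
            (row for row in block if row[0] == reference), None
        )
        if ref is None:
            continue
        chrom_sizes.setdefault(ref[1], ref[5])
        for row in block:
            if row[0] not in taxa:
                taxa.append(row[0])

    out: dict[str, dict[str, np.ndarray]] = {
        chrom: {t: np.full(size, b"N", dtype="S1") for t in taxa}
        for chrom, size in chrom_sizes.items()
    }
    for block in blocks:
        ref = block[0] if reference is None else next(
            (row for row in block if row[0] == reference), None
        )
        if ref is None:
            continue
        taxon_r, chrom, start, size, strand, _, text = ref
        if strand != "+":
            raise ValueError("reference rows must be on the + strand")
        ref_arr = np.frombuffer(text.upper().encode(), dtype="S1")
        keep = ref_arr != b"-"
        positions = start + np.arange(int(keep.sum()))
        for taxon, _c, _s, _sz, _st, _ss, txt in block:
            row = np.frombuffer(txt.upper().encode(), dtype="S1")
            if len(row) != len(ref_arr):
                raise ValueError("ragged MAF block")
            out[chrom][taxon][positions] = row[keep]
    return {
        chrom: {t: arr.tobytes().decode() for t, arr in rows.items()}
        for chrom, rows in out.items()
    }


def write_manifest(path: str | Path, windows: Sequence[AlignmentWindow]) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "window_id": [f"w{i:06d}" for i in range(len(windows))],
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "repeat_flag": [float(w.repeat_flag) for w in windows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
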