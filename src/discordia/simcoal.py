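"""Multispecies-coalescent simulation of windowed alignments with introgression.

The generator emulates a whole-genome-alignment product cut into
recombinationally independent windows: each window is an independent draw of
a coalescent gene tree inside a species tree whose branch lengths are in
coalescent units, optionally perturbed by pulse introgression events, and
sequences are evolved on that gene tree under Jukes-Cantor. Free
recombination between windows, none within.

Time runs backward from the present (0) in coalescent units: within every
species-tree branch each pair of lineages coalesces independently at rate 1,
and at an introgression pulse each lineage currently in the recipient
population jumps to the donor population with probability gamma.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._phylo import Node, Tree, parse_newick
from .winio import AlignmentWindow, write_fasta

__all__ = [
    "ConfigurationError",
    "SpeciesTreeModel",
    "IntrogressionEvent",
    "SimConfig",
    "SimulatedDataset",
    "sample_gene_tree",
    "evolve_sequences",
    "simulate_windows",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    """A model/event combination that cannot be simulated."""


@dataclass(frozen=True)
class IntrogressionEvent:
    """A pulse of gene flow: backward in time, lineages in ``recipient``
    switch to ``donor`` with probability ``proportion`` at ``time``.

    Branches are named by a leaf label, or by a tuple of leaf labels for the
    branch above their most recent common ancestor.
    """

    donor: str | tuple[str, ...]
    recipient: str | tuple[str, ...]
    time: float
    proportion: float

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ConfigurationError(
                f"introgression proportion must be in [0,1], got {self.proportion}"
            )
        if self.time < 0:
            raise ConfigurationError("introgression time must be >= 0")

    def donor_clade(self) -> frozenset[str]:
        return _as_clade(self.donor)

    def recipient_clade(self) -> frozenset[str]:
        return _as_clade(self.recipient)


def _as_clade(spec: str | tuple[str, ...]) -> frozenset[str]:
    if isinstance(spec, str):
        return frozenset((spec,))
    return frozenset(spec)


class SpeciesTreeModel:
    """Rooted binary species tree with branch lengths in coalescent units.

    Each branch is a panmictic population; the branch above the root (the
    root stem) extends to infinity. Branches are addressed by the frozenset
    of leaf labels below them.
    """

    def __init__(self, tree: Tree):
        self.tree = tree
        labels = tree.leaf_labels()
        if not labels:
            raise ConfigurationError("species tree has no leaves")
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate taxon labels in species tree")
        self.taxa = tuple(sorted(labels))
        # node ages from leaves (age 0) upward; must be consistent (ultrametric)
        self._ages: dict[frozenset[str], float] = {}
        self._children: dict[frozenset[str], list[frozenset[str]]] = {}
        self._parent: dict[frozenset[str], frozenset[str]] = {}

        def rec(n: Node) -> tuple[frozenset[str], float]:
            if n.is_leaf:
                clade = frozenset((n.label,))
                self._ages[clade] = 0.0
                self._children[clade] = []
                return clade, 0.0
            if len(n.children) != 2:
                raise ConfigurationError("species tree must be strictly binary")
            kids = []
            age = None
            for c in n.children:
                clade_c, age_c = rec(c)
                if c.length is None or c.length < 0:
                    raise ConfigurationError(
                        "species tree branch lengths must be present and >= 0"
                    )
                kids.append(clade_c)
                a = age_c + c.length
                if age is None:
                    age = a
                elif not math.isclose(age, a, rel_tol=1e-9, abs_tol=1e-9):
                    raise ConfigurationError(
                        "species tree is not ultrametric in coalescent time "
                        f"(node ages {age} vs {a})"
                    )
            clade = kids[0] | kids[1]
            self._ages[clade] = float(age)  # type: ignore[arg-type]
            self._children[clade] = kids
            for k in kids:
                self._parent[k] = clade
            return clade, float(age)  # type: ignore[return-value]

        self.root_clade, self.root_age = rec(tree.root)

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTreeModel":
        return cls(parse_newick(text))

    # population (branch) intervals ----------------------------------------

    def branch_interval(self, clade: frozenset[str]) -> tuple[float, float]:
        """[start, end) of the population's existence, end = inf for the root."""
        if clade not in self._ages:
            raise KeyError(f"no species-tree branch with leaf set {sorted(clade)}")
        lo = self._ages[clade]
        hi = self._ages[self._parent[clade]] if clade in self._parent else math.inf
        return lo, hi

    def clades(self) -> list[frozenset[str]]:
        return list(self._ages)

    def node_age(self, clade: frozenset[str]) -> float:
        return self._ages[clade]

    def children_of(self, clade: frozenset[str]) -> list[frozenset[str]]:
        return self._children[clade]

    def validate_events(self, events: Iterable[IntrogressionEvent]) -> None:
        for ev in events:
            for role, clade in (
                ("donor", ev.donor_clade()),
                ("recipient", ev.recipient_clade()),
            ):
                lo, hi = self.branch_interval(clade)
                if not (lo <= ev.time < hi):
                    raise ConfigurationError(
                        f"event time {ev.time} outside the {role} branch "
                        f"{sorted(clade)} interval [{lo}, {hi})"
                    )
            if ev.donor_clade() == ev.recipient_clade():
                raise ConfigurationError("donor and recipient branches coincide")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the window simulator; defaults mirror the emulated study
    design (10-kb windows, one haploid genome per species)."""

    n_windows: int = 100
    window_length: int = 10_000
    mutation_scale: float = 0.01  # expected substitutions/site per coalescent unit
    seed: int = 0
    samples_per_taxon: int = 1
    repeat_fraction: float = 0.0
    missing_fraction: float = 0.0
    chrom: str = "chr1"

    def __post_init__(self):
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.mutation_scale < 0:
            raise ValueError("mutation_scale must be >= 0")
        for name in ("repeat_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.samples_per_taxon < 1:
            raise ValueError("samples_per_taxon must be >= 1")


@dataclass
class SimulatedDataset:
    windows: list[AlignmentWindow]
    true_gene_trees: list[Tree]
    model: SpeciesTreeModel
    events: list[IntrogressionEvent]
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        """FASTA per window + manifest TSV + truth JSON + true trees newick."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        windir = outdir / "windows"
        windir.mkdir(exist_ok=True)
        with open(outdir / "windows.tsv", "w") as manifest:
            manifest.write("window_id\tchrom\tstart\tend\trepeat_flag\n")
            for i, w in enumerate(self.windows):
                wid = f"w{i:06d}"
                write_fasta(windir / f"{wid}.fa", w.sequences)
                manifest.write(
                    f"{wid}\t{w.chrom}\t{w.start}\t{w.end}\t{int(bool(w.repeat_flag))}\n"
                )
        with open(outdir / "true_gene_trees.nwk", "w") as fh:
            for t in self.true_gene_trees:
                fh.write(t.to_newick() + "\n")
        truth = {
            "species_tree": self.model.tree.to_newick(),
            "events": [
                {
                    "donor": sorted(ev.donor_clade()),
                    "recipient": sorted(ev.recipient_clade()),
                    "time": ev.time,
                    "proportion": ev.proportion,
                }
                for ev in self.events
            ],
            "seed": self.config.seed,
            "n_windows": self.config.n_windows,
            "window_length": self.config.window_length,
            "mutation_scale": self.config.mutation_scale,
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)


# ---------------------------------------------------------------------------
# Gene-tree sampling
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("node", "age")

    def __init__(self, node: Node, age: float):
        self.node = node
        self.age = age


def sample_gene_tree(
    model: SpeciesTreeModel,
    events: Sequence[IntrogressionEvent] = (),
    rng: Optional[np.random.Generator] = None,
    samples_per_taxon: int = 1,
) -> Tree:
    """Draw one gene tree under the MSC with pulse introgression.

    Returns a rooted tree with branch lengths in coalescent units. With a
    single sampled lineage in total the result is a single-leaf tree.
    """
    if rng is None:
        rng = np.random.default_rng()
    if samples_per_taxon < 1:
        raise ValueError("need at least one sampled lineage per taxon")
    model.validate_events(events)

    pops: dict[frozenset[str], list[_Lineage]] = {c: [] for c in model.clades()}
    n_total = 0
    for taxon in model.taxa:
        clade = frozenset((taxon,))
        for k in range(samples_per_taxon):
            label = taxon if samples_per_taxon == 1 else f"{taxon}_{k + 1}"
            pops[clade].append(_Lineage(Node(label), 0.0))
            n_total += 1

    # schedule: speciations (children merge into parent) and pulses, in time
    # order; at equal times speciations are applied first so a pulse at a
    # node age addresses the post-merge population.
    schedule: list[tuple[float, int, object]] = []
    for clade in model.clades():
        if model.children_of(clade):
            schedule.append((model.node_age(clade), 0, clade))
    for ev in events:
        schedule.append((ev.time, 1, ev))
    schedule.sort(key=lambda x: (x[0], x[1]))

    t = 0.0
    i = 0
    while True:
        t_next = schedule[i][0] if i < len(schedule) else math.inf
        t = _coalesce_until(pops, t, t_next, rng)
        if i >= len(schedule):
            break
        _, kind, payload = schedule[i]
        i += 1
        t = t_next
        if kind == 0:
            clade = payload  # type: ignore[assignment]
            merged = []
            for ch in model.children_of(clade):  # type: ignore[arg-type]
                merged.extend(pops.pop(ch))
            pops[clade].extend(merged)  # type: ignore[index]
        else:
            ev = payload  # type: ignore[assignment]
            rec_pop = pops[ev.recipient_clade()]
            stay: list[_Lineage] = []
            for lin in rec_pop:
                if rng.random() < ev.proportion:
                    pops[ev.donor_clade()].append(lin)
                else:
                    stay.append(lin)
            pops[ev.recipient_clade()] = stay

        remaining = sum(len(v) for v in pops.values())
        if remaining == 1 and i >= len(schedule):
            break

    (last,) = [lin for v in pops.values() for lin in v]
    _fill_lengths(last.node, last.age)
    return Tree(last.node)


def _coalesce_until(
    pops: dict[frozenset[str], list[_Lineage]],
    t: float,
    t_end: float,
    rng: np.random.Generator,
) -> float:
    """Coalesce lineages within each population until t_end (may be inf)."""
    while True:
        active = [(c, v) for c, v in pops.items() if len(v) >= 2]
        if not active:
            return min(t_end, t) if t_end < math.inf else t
        rates = np.array([len(v) * (len(v) - 1) / 2.0 for _, v in active])
        total = rates.sum()
        wait = rng.exponential(1.0 / total)
        if t + wait >= t_end:
            return t_end
        t += wait
        idx = rng.choice(len(active), p=rates / total)
        clade, lineages = active[idx]
        k = len(lineages)
        a, b = rng.choice(k, size=2, replace=False)
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        la, lb = lineages[a], lineages[b]
        parent = Node(None)
        parent.add(la.node)
        parent.add(lb.node)
        la.node.length = t - la.age
        lb.node.length = t - lb.age
        new = _Lineage(parent, t)
        del lineages[b]
        lineages[a] = new


def _fill_lengths(root: Node, root_age: float) -> None:
    """Branch lengths below the MRCA were set at coalescence; the root itself
    has no branch. Leaf lengths of a never-coalesced lineage are left as the
    lineage age (single-sample degenerate case)."""
    root.length = None
    _ = root_age


# ---------------------------------------------------------------------------
# Sequence evolution (Jukes-Cantor)
# ---------------------------------------------------------------------------


def evolve_sequences(
    tree: Tree,
    length: int,
    mutation_scale: float,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, str]:
    """Evolve one alignment column set of ``length`` sites down ``tree``.

    Each site evolves independently under JC69; the expected number of
    substitutions on a branch is ``branch_length * mutation_scale``. Returns
    leaf label -> sequence (uppercase ACGT, no gaps).
    """
    if rng is None:
        rng = np.random.default_rng()
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    if mutation_scale < 0:
        raise ValueError("mutation_scale must be >= 0")

    out: dict[str, str] = {}
    root_states = rng.integers(0, 4, size=length)

    def rec(node: Node, states: np.ndarray) -> None:
        if node.is_leaf:
            if node.label is None:
                raise ValueError("gene tree has an unlabelled leaf")
            out[node.label] = _BASES[states].tobytes().decode()
            return
        for child in node.children:
            bl = child.length if child.length is not None else 0.0
            d = bl * mutation_scale
            if d > 0:
                p_diff = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
                mask = rng.random(length) < p_diff
                nmut = int(mask.sum())
                child_states = states.copy()
                if nmut:
                    child_states[mask] = (
                        child_states[mask] + rng.integers(1, 4, size=nmut)
                    ) % 4
            else:
                child_states = states
            rec(child, child_states)

    rec(tree.root, root_states)
    return out


# ---------------------------------------------------------------------------
# Window simulation
# ---------------------------------------------------------------------------


def simulate_windows(
    config: SimConfig,
    model: SpeciesTreeModel,
    events: Sequence[IntrogressionEvent] = (),
) -> SimulatedDataset:
    """One independent gene tree and alignment per window, laid end-to-end on
    one synthetic chromosome. Fixed seed -> byte-identical dataset."""
    model.validate_events(events)
    rng = np.random.default_rng(config.seed)
    windows: list[AlignmentWindow] = []
    trees: list[Tree] = []
    L = config.window_length
    for i in range(config.n_windows):
        gtree = sample_gene_tree(
            model, events, rng, samples_per_taxon=config.samples_per_taxon
        )
        seqs = evolve_sequences(gtree, L, config.mutation_scale, rng)
        seqs = {name: seqs[name] for name in sorted(seqs)}
        if config.missing_fraction > 0:
            seqs = {
                k: _inject_missing(v, config.missing_fraction, rng)
                for k, v in seqs.items()
            }
        repeat = bool(rng.random() < config.repeat_fraction)
        windows.append(
            AlignmentWindow(
                sequences=seqs,
                chrom=config.chrom,
                start=i * L,
                end=(i + 1) * L,
                repeat_flag=repeat,
            )
        )
        trees.append(gtree)
    return SimulatedDataset(
        windows=windows,
        true_gene_trees=trees,
        model=model,
        events=list(events),
        config=config,
    )


def _inject_missing(seq: str, fraction: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < fraction
    arr[mask] = b"N"
    return arr.tobytes().decode()
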