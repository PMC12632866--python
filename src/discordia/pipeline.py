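"""End-to-end orchestration: simulate/load -> window -> filter -> gene trees
-> concordance & regional stratification -> D-statistics -> D_FOIL.

A run is a pure function of its :class:`RunConfig` (including the seed):
identical configs produce byte-identical summary files. Every stage writes
its own machine-readable table and the consolidated summary collects the
headline results plus a provenance record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from ._phylo import Tree, parse_newick, read_newick_trees
from . import concord, dstat, dfoil, simcoal, treebuild, winio

__all__ = ["RunConfig", "StageError", "EmptyResultError", "run_pipeline",
           "DEFAULT_SPECIES_TREE"]

log = logging.getLogger(__name__)

#: Demo species-tree model: a five-species ingroup clade with a short
#: internal branch (high incomplete lineage sorting) plus a distant
#: outgroup; branch lengths in coalescent units.
DEFAULT_SPECIES_TREE = (
    "((((rerio:1.0,aesculapii:1.0):0.1,kyathit:1.1):1.9,"
    "(tinwini:1.5,nigrofasciatus:1.5):1.5):1.0,albolineatus:4.0);"
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class EmptyResultError(StageError):
    """The run finished cleanly but produced no analyzable gene trees."""


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | alignments | trees
    outdir: str = "discordia_run"
    seed: int = 0
    outgroup: str = "albolineatus"
    species_tree: Optional[str] = DEFAULT_SPECIES_TREE  # newick (or path)
    events: list[dict] = field(default_factory=list)
    # simulation
    n_windows: int = 100
    window_length: int = 10_000
    mutation_scale: float = 0.01
    repeat_fraction: float = 0.0
    missing_fraction: float = 0.0
    # inputs for the other modes
    alignments: dict = field(default_factory=dict)  # chrom -> FASTA path
    trees_file: Optional[str] = None
    # window & site filters
    window_size: int = 10_000
    min_window_len: int = 150
    max_repeat_fraction: float = 0.0
    max_missing: float = 0.2
    thin: int = 0
    # gene trees
    bootstrap: int = 0
    monophyly_clade: list = field(default_factory=list)
    # concordance / regional
    focal_taxa: list = field(default_factory=list)
    min_trees_per_chrom: int = 20
    n_bins: int = 5
    max_exhaustive: int = 8
    # D statistics
    n_jackknife_blocks: int = 20
    dfoil_families: list = field(default_factory=list)
    dfoil_alpha: float = 0.01

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if self.mode not in ("simulate", "alignments", "trees"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "alignments" and not self.alignments:
            raise ValueError("alignments mode needs an 'alignments' mapping")
        if self.mode == "trees" and not self.trees_file:
            raise ValueError("trees mode needs 'trees_file'")


def _load_newick_text(spec: str) -> str:
    """A newick string is used verbatim; anything else is read as a path."""
    if "(" in spec:
        return spec
    return Path(spec).read_text()


def _events_from_config(cfg: RunConfig) -> list[simcoal.IntrogressionEvent]:
    out = []
    for ev in cfg.events:
        donor = ev["donor"]
        recipient = ev["recipient"]
        out.append(
            simcoal.IntrogressionEvent(
                donor=tuple(donor) if isinstance(donor, list) else donor,
                recipient=tuple(recipient) if isinstance(recipient, list) else recipient,
                time=float(ev["time"]),
                proportion=float(ev["proportion"]),
            )
        )
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order and write the report bundle.

    Returns the consolidated summary dict (also written to
    ``<outdir>/summary.json``). Raises :class:`StageError` naming the failed
    stage; partial outputs are retained.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"stages": {}}
    model: Optional[simcoal.SpeciesTreeModel] = None
    species_tree: Optional[Tree] = None

    # ----------------------------------------------------------- input stage
    windows: list[winio.AlignmentWindow] = []
    chrom_lengths: dict[str, int] = {}
    try:
        if cfg.mode == "simulate":
            nwk = _load_newick_text(cfg.species_tree or DEFAULT_SPECIES_TREE)
            model = simcoal.SpeciesTreeModel.from_newick(nwk)
            species_tree = model.tree
            events = _events_from_config(cfg)
            sim_cfg = simcoal.SimConfig(
                n_windows=cfg.n_windows,
                window_length=cfg.window_length,
                mutation_scale=cfg.mutation_scale,
                seed=cfg.seed,
                repeat_fraction=cfg.repeat_fraction,
                missing_fraction=cfg.missing_fraction,
            )
            dataset = simcoal.simulate_windows(sim_cfg, model, events)
            dataset.write(outdir / "sim")
            windows = dataset.windows
            chrom_lengths = {sim_cfg.chrom: cfg.n_windows * cfg.window_length}
        elif cfg.mode == "alignments":
            for chrom, path in sorted(cfg.alignments.items()):
                aln = winio.read_fasta(path)
                chrom_lengths[chrom] = len(next(iter(aln.values())))
                windows.extend(
                    winio.make_windows(aln, window_size=cfg.window_size, chrom=chrom)
                )
            if cfg.species_tree:
                species_tree = parse_newick(_load_newick_text(cfg.species_tree))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", str(exc)) from exc
    summary["stages"]["windows_cut"] = len(windows)
    log.info("windows cut: %d", len(windows))

    # ------------------------------------------------------------ gene trees
    gene_trees: list[Tree] = []
    tree_windows: list[Optional[winio.AlignmentWindow]] = []
    rejected = 0
    try:
        if cfg.mode == "trees":
            gene_trees = read_newick_trees(cfg.trees_file)
            tree_windows = [None] * len(gene_trees)
            if cfg.species_tree:
                species_tree = parse_newick(cfg.species_tree)
            summary["stages"]["trees_read"] = len(gene_trees)
        else:
            kept = winio.filter_windows(
                windows,
                min_len=cfg.min_window_len,
                max_repeat_fraction=cfg.max_repeat_fraction,
            )
            summary["stages"]["windows_filtered"] = len(kept)
            log.info("windows after filters: %d", len(kept))
            rng = np.random.default_rng(cfg.seed + 1)
            for w in kept:
                try:
                    if cfg.bootstrap > 0:
                        t = treebuild.bootstrap_support(w, b=cfg.bootstrap, rng=rng)
                    else:
                        t = treebuild.nj_from_window(w)
                    t = treebuild.root_by_outgroup(t, cfg.outgroup)
                except (treebuild.WindowRejected, ValueError) as exc:
                    log.info("window %s:%d-%d rejected: %s", w.chrom, w.start, w.end, exc)
                    rejected += 1
                    continue
                gene_trees.append(t)
                tree_windows.append(w)
            summary["stages"]["windows_rejected_inference"] = rejected
            windows = kept
    except StageError:
        raise
    except Exception as exc:
        raise StageError("gene_trees", str(exc)) from exc

    if cfg.monophyly_clade:
        before = len(gene_trees)
        keep_idx = [
            i
            for i, t in enumerate(gene_trees)
            if treebuild.monophyly_filter([t], cfg.monophyly_clade, outgroup=cfg.outgroup)
        ]
        gene_trees = [gene_trees[i] for i in keep_idx]
        tree_windows = [tree_windows[i] for i in keep_idx]
        summary["stages"]["trees_after_monophyly"] = len(gene_trees)
        log.info("monophyly filter: %d -> %d trees", before, len(gene_trees))

    summary["stages"]["gene_trees"] = len(gene_trees)

    # topology frequencies -------------------------------------------------
    focal = cfg.focal_taxa or None
    counts = treebuild.count_topologies(gene_trees, restrict_to=focal)
    counts.to_csv(outdir / "topology_counts.tsv", sep="\t", index=False)
    summary["topology_counts"] = counts.to_dict(orient="records")

    if not gene_trees:
        summary["status"] = "empty"
        _finalize(outdir, cfg, summary)
        raise EmptyResultError("gene_trees", "no gene trees survive the filters")

    # species tree ---------------------------------------------------------
    try:
        if species_tree is None:
            taxa = sorted(frozenset().union(*(t.taxon_set() for t in gene_trees)))
            species_tree, score, ties = concord.quartet_score_species_tree(
                gene_trees, taxa, max_exhaustive=cfg.max_exhaustive
            )
            summary["species_tree_estimated"] = {
                "newick": species_tree.to_newick(lengths=False),
                "quartet_score": score,
                "ties": ties,
            }
        summary["species_tree"] = species_tree.to_newick(lengths=False)
    except Exception as exc:
        raise StageError("species_tree", str(exc)) from exc

    # quartet frequencies around focal branches ----------------------------
    try:
        qrows = []
        for br in concord.focal_branches(species_tree):
            qf = concord.quartet_frequencies(gene_trees, br)
            qrows.append(
                {
                    "branch_id": br.branch_id,
                    "t1": qf.t1,
                    "t2": qf.t2,
                    "t3": qf.t3,
                    "n_trees": qf.n_trees,
                }
            )
        qdf = pd.DataFrame(qrows)
        qdf.to_csv(outdir / "quartet_frequencies.tsv", sep="\t", index=False)
        summary["quartet_frequencies"] = qrows
    except Exception as exc:
        raise StageError("concordance", str(exc)) from exc

    # regional stratification ----------------------------------------------
    if chrom_lengths and any(w is not None for w in tree_windows):
        try:
            rows = []
            for w, t in zip(tree_windows, gene_trees):
                if w is None:
                    continue
                rows.append(
                    {
                        "chrom": w.chrom,
                        "start": w.start,
                        "end": w.end,
                        "topology": treebuild.canonical_topology(t, restrict_to=focal),
                    }
                )
            wdf = pd.DataFrame(rows)
            table, chi2, p, excluded = concord.regional_topology_frequencies(
                wdf,
                chrom_lengths,
                min_trees_per_chrom=cfg.min_trees_per_chrom,
                n_bins=cfg.n_bins,
            )
            table.to_csv(outdir / "regional_topologies.tsv", sep="\t", index=False)
            summary["regional"] = {
                "chi2": None if pd.isna(chi2) else chi2,
                "p": None if pd.isna(p) else p,
                "excluded_chromosomes": excluded,
            }
        except Exception as exc:
            raise StageError("regional", str(exc)) from exc

    # D statistics ----------------------------------------------------------
    if cfg.mode != "trees" and windows:
        try:
            snps = winio.extract_biallelic_sites(
                windows, outgroup=cfg.outgroup, max_missing=cfg.max_missing,
                thin=cfg.thin,
            )
            summary["stages"]["snps"] = snps.n_sites
            log.info("SNP sites retained: %d", snps.n_sites)
            ingroup = [t for t in snps.taxa if t != cfg.outgroup]
            if len(ingroup) >= 3 and snps.n_sites > 0:
                dtable = dstat.dtrios_scan(
                    snps, outgroup=cfg.outgroup, n_blocks=cfg.n_jackknife_blocks
                )
                dtable.to_csv(outdir / "dstat_trios.tsv", sep="\t", index=False)
                best = dstat.best_per_pair(dtable)
                best.to_csv(outdir / "dstat_best_per_pair.tsv", sep="\t", index=False)
                summary["dstat"] = dtable.to_dict(orient="records")
            if cfg.dfoil_families and snps.n_sites > 0:
                pair_ages = None
                if model is not None:
                    pair_ages = {
                        frozenset((a, b)): _mrca_age(model, a, b)
                        for fam in cfg.dfoil_families
                        for a, b in ((fam[0], fam[1]), (fam[2], fam[3]))
                    }
                ftable = dfoil.dfoil_scan(
                    snps,
                    [tuple(f) for f in cfg.dfoil_families],
                    alpha=cfg.dfoil_alpha,
                    pair_ages=pair_ages,
                )
                ftable.to_csv(outdir / "dfoil.tsv", sep="\t", index=False)
                summary["dfoil"] = ftable.to_dict(orient="records")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("dstat", str(exc)) from exc

    summary["status"] = "ok"
    _finalize(outdir, cfg, summary)
    return summary


def _mrca_age(model: simcoal.SpeciesTreeModel, a: str, b: str) -> float:
    best = None
    for clade in model.clades():
        if {a, b} <= clade and (best is None or len(clade) < len(best)):
            best = clade
    if best is None:
        raise ValueError(f"no common ancestor of {a}, {b} in the species tree")
    return model.node_age(best)


def _finalize(outdir: Path, cfg: RunConfig, summary: dict) -> None:
    provenance = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "versions": {
            "discordia": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and pd.isna(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
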