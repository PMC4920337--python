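"""Readers/writers, posterior summaries, and the experiment-grid driver.

Matrices travel as NEXUS (MrBayes dialect: ``?`` missing, ``-`` gap, charset
commands in a sets block), trees as Newick, traces and summary tables as
TSV, density curves as (x, y) pairs -- no binary formats.  Posterior age
distributions are summarized by the median and the 95% highest-posterior-
density interval; clade ages are computed on fossil-pruned tree samples.
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from tedkit.timetree import TimeTree, FossilTable, prune_fossils, ghost_excess
from tedkit.char_models import MorphMatrix, MolAlignment

__all__ = [
    "TraceSummary",
    "CladeAgeSummary",
    "ConsensusTree",
    "read_nexus",
    "write_nexus",
    "hpd",
    "kde",
    "summarize_clade_ages",
    "majority_consensus",
    "GridCell",
    "run_experiment_grid",
]


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

def write_nexus(data: MorphMatrix | MolAlignment, path_or_buf) -> None:
    """Write a character matrix as a MrBayes-dialect NEXUS file.

    Morphology uses datatype=standard with digit symbols; alignments use
    datatype=dna and append a sets block with one charset per partition.
    """
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    if isinstance(data, MorphMatrix):
        kmax = int(data.k.max())
        symbols = "".join(str(i) for i in range(kmax))
        buf.write(f"  DIMENSIONS NTAX={data.n_taxa} NCHAR={data.n_chars};\n")
        buf.write(f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" '
                  'MISSING=? GAP=-;\n  MATRIX\n')
        for i, taxon in enumerate(data.taxa):
            row = "".join("?" if s < 0 else str(int(s))
                          for s in data.states[i])
            buf.write(f"    {_nexus_name(taxon)}  {row}\n")
        buf.write("  ;\nEND;\n")
        # per-character state counts, so k survives a round trip even when
        # some states are unobserved
        buf.write("\n[&tedkit_k " + " ".join(str(int(k)) for k in data.k)
                  + "]\n")
    elif isinstance(data, MolAlignment):
        buf.write(f"  DIMENSIONS NTAX={data.n_taxa} NCHAR={data.n_sites};\n")
        buf.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        alphabet = "ACGT"
        for i, taxon in enumerate(data.taxa):
            row = "".join("?" if s < 0 else alphabet[s]
                          for s in data.sites[i])
            buf.write(f"    {_nexus_name(taxon)}  {row}\n")
        buf.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for pi, name in enumerate(data.partition_names):
            sites = np.where(data.partition_map == pi)[0] + 1
            buf.write(f"  CHARSET {name} = {_ranges(sites)};\n")
        buf.write("END;\n")
    else:
        raise TypeError(f"unsupported data type {type(data).__name__}")
    text = buf.getvalue()
    if isinstance(path_or_buf, str):
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    else:
        path_or_buf.write(text)


def _nexus_name(name: str) -> str:
    return name if re.fullmatch(r"[\w.]+", name) else f"'{name}'"


def _ranges(sites: np.ndarray) -> str:
    """Compact 1-based site list into NEXUS range syntax (with \\3 strides)."""
    sites = np.sort(sites)
    if sites.size >= 3:
        step = sites[1] - sites[0]
        if step > 1 and np.all(np.diff(sites) == step):
            return f"{sites[0]}-{sites[-1]}\\{step}"
    parts = []
    start = prev = int(sites[0])
    for s in sites[1:]:
        s = int(s)
        if s == prev + 1:
            prev = s
            continue
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = s
    parts.append(f"{start}-{prev}" if prev > start else f"{start}")
    return " ".join(parts)


def read_nexus(path_or_buf) -> MorphMatrix | MolAlignment:
    """Read a NEXUS character matrix (interleaved or not, MrBayes dialect).

    Standard-datatype blocks become :class:`MorphMatrix` with per-character
    state counts inferred from the observed symbols (or restored from the
    embedded state-count comment, if present); DNA blocks become
    :class:`MolAlignment` with partitions taken from charset commands.
    """
    if isinstance(path_or_buf, str):
        with open(path_or_buf) as fh:
            text = fh.read()
    else:
        text = path_or_buf.read()
    m = re.search(r"DATATYPE\s*=\s*(\w+)", text, re.IGNORECASE)
    if not m:
        raise ValueError("no DATATYPE declaration found")
    datatype = m.group(1).lower()
    if datatype == "standard":
        mat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus",
                                                  preserve_underscores=True)
        taxa = [t.label for t in mat.taxon_namespace]
        rows = []
        for t in mat.taxon_namespace:
            row = []
            for cell in mat[t]:
                sym = str(cell.symbol) if cell is not None else "?"
                row.append(-1 if sym in "?-" else int(sym))
            rows.append(row)
        states = np.array(rows, dtype=np.int8)
        km = re.search(r"\[&tedkit_k ([\d ]+)\]", text)
        if km:
            k = np.array([int(x) for x in km.group(1).split()])
        else:
            k = np.maximum(states.max(axis=0) + 1, 2)
        variable = []
        for j in range(states.shape[1]):
            obs = states[:, j][states[:, j] >= 0]
            variable.append(obs.size > 0 and not np.all(obs == obs[0]))
        return MorphMatrix(taxa, states, k, variable_only=all(variable))
    if datatype == "dna":
        mat = dendropy.DnaCharacterMatrix.get(data=text, schema="nexus",
                                            preserve_underscores=True)
        taxa = [t.label for t in mat.taxon_namespace]
        lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
        rows = []
        for t in mat.taxon_namespace:
            row = [lookup.get(str(cell.symbol).upper(), -1) for cell in mat[t]]
            rows.append(row)
        sites = np.array(rows, dtype=np.int8)
        n_sites = sites.shape[1]
        charsets = _parse_charsets(text, n_sites)
        if charsets:
            pmap = np.zeros(n_sites, dtype=np.int64)
            names = []
            for pi, (name, idx) in enumerate(charsets.items()):
                pmap[idx] = pi
                names.append(name)
        else:
            pmap = np.zeros(n_sites, dtype=np.int64)
            names = ["all"]
        return MolAlignment(taxa, sites, pmap, names)
    raise ValueError(f"unsupported datatype {datatype!r}")


def _parse_charsets(text: str, n_sites: int) -> dict[str, np.ndarray]:
    """Parse MrBayes-style charset commands: ranges, lists, and codon-position
    strides like ``1-1500\\3``."""
    out: dict[str, np.ndarray] = {}
    for m in re.finditer(r"charset\s+(\S+)\s*=\s*([^;]+);", text,
                         re.IGNORECASE):
        name, body = m.group(1), m.group(2)
        idx: list[int] = []
        for token in body.split():
            mm = re.fullmatch(r"(\d+)(?:-(\d+|\.))?(?:\\(\d+))?", token)
            if not mm:
                raise ValueError(f"cannot parse charset token {token!r}")
            start = int(mm.group(1))
            end = n_sites if mm.group(2) in (".",) else \
                int(mm.group(2)) if mm.group(2) else start
            step = int(mm.group(3)) if mm.group(3) else 1
            idx.extend(range(start - 1, end, step))
        out[name] = np.array(sorted(set(idx)), dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing the requested posterior mass (empirical:
    the shortest window over the sorted samples)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError("need >= 10 samples for an HPD interval")
    k = max(int(np.ceil(mass * n)), 2)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def kde(samples: Sequence[float], bandwidth_adjust: float = 3.0,
        n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density with a Silverman reference bandwidth scaled
    by ``bandwidth_adjust`` (posterior age densities are customarily drawn
    heavily smoothed, adjust in [2, 5]).  Returns (x, density) with the
    curve integrating to ~1; degenerate samples yield a narrow spike."""
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 samples for a KDE")
    if np.std(x) == 0:
        center = float(x[0])
        width = max(abs(center) * 1e-6, 1e-6)
        grid = np.linspace(center - 5 * width, center + 5 * width, n_grid)
        dens = sp_stats.norm.pdf(grid, center, width)
        return grid, dens
    k = sp_stats.gaussian_kde(x, bw_method="silverman")
    k.set_bandwidth(k.factor * bandwidth_adjust)
    bw = np.sqrt(k.covariance[0, 0])
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    return grid, k(grid)


@dataclass
class TraceSummary:
    """Median + 95% HPD + ESS per scalar parameter, with provenance."""

    table: pd.DataFrame
    config_hash: str = ""
    seed: int = 0

    @classmethod
    def from_trace(cls, trace: pd.DataFrame, params: Sequence[str] | None = None,
                   config_hash: str = "", seed: int = 0) -> "TraceSummary":
        import arviz as az
        if "burnin" in trace.columns:
            trace = trace[~trace["burnin"]]
        if params is None:
            skip = {"gen", "burnin"}
            params = [c for c in trace.columns if c not in skip
                      and np.issubdtype(trace[c].dtype, np.number)]
        rows = []
        for p in params:
            x = trace[p].to_numpy()
            lo, hi = hpd(x)
            med = float(np.median(x))
            if np.std(x) == 0:
                ess = float(len(x))
            else:
                ess = float(az.ess(np.asarray(x)[None, :]))
            assert lo <= med <= hi or np.isclose(lo, med) or np.isclose(med, hi)
            rows.append({"parameter": p, "median": med,
                         "hpd_low": lo, "hpd_high": hi, "ess": ess})
        return cls(pd.DataFrame(rows).set_index("parameter"),
                   config_hash, seed)


@dataclass
class CladeAgeSummary:
    """Clade crown ages from fossil-pruned tree samples.

    ``table`` has one row per clade: median, 95% HPD bounds (Ma) and the
    frequency with which the clade was non-monophyletic in the samples (the
    MRCA age is used for those samples, and reported separately when the
    two conventions differ by more than 1 Myr).
    """

    table: pd.DataFrame
    config_hash: str = ""
    seed: int = 0


def summarize_clade_ages(tree_samples: Sequence[TimeTree],
                         clades: Mapping[str, Sequence[str]],
                         config_hash: str = "", seed: int = 0
                         ) -> CladeAgeSummary:
    """Median + 95% HPD of each clade's crown age across tree samples.

    Fossils are pruned from each sample first.  For samples in which the
    clade is non-monophyletic, the MRCA age is used and the non-monophyly
    frequency is reported.
    """
    if not tree_samples:
        raise ValueError("no tree samples")
    rows = []
    pruned = [prune_fossils(t) if t.fossil_tips() else t
              for t in tree_samples]
    for name, taxa in clades.items():
        taxa = set(taxa)
        ages, mono_ages, non_mono = [], [], 0
        for t in pruned:
            node = t.mrca(taxa)
            sub = {tip.label for tip in TimeTree(node, validate=False).tips()} \
                if not node.is_tip else {node.label}
            age = node.age
            ages.append(age)
            if sub == taxa:
                mono_ages.append(age)
            else:
                non_mono += 1
        ages = np.array(ages)
        lo, hi = hpd(ages) if ages.size >= 10 else (ages.min(), ages.max())
        row = {"clade": name, "median": float(np.median(ages)),
               "hpd_low": float(lo), "hpd_high": float(hi),
               "non_monophyly_freq": non_mono / len(pruned)}
        if mono_ages and non_mono:
            med_mono = float(np.median(mono_ages))
            if abs(med_mono - row["median"]) > 1.0:
                row["median_monophyletic_only"] = med_mono
        rows.append(row)
    return CladeAgeSummary(pd.DataFrame(rows).set_index("clade"),
                           config_hash, seed)


@dataclass
class ConsensusTree:
    """50%-majority-rule consensus with clade posterior probabilities."""

    tree: dendropy.Tree
    clade_pp: dict[frozenset, float]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def majority_consensus(tree_samples: Sequence[TimeTree]) -> ConsensusTree:
    """Majority-rule consensus over tree samples sharing one taxon set;
    clade posterior probability = sampling frequency."""
    if not tree_samples:
        raise ValueError("no tree samples")
    taxa = set(tree_samples[0].taxa())
    counts: dict[frozenset, int] = {}
    for t in tree_samples:
        if set(t.taxa()) != taxa:
            raise ValueError("tree samples must share one taxon set")
        for node in t.internal_nodes():
            clade = frozenset(
                tip.label for tip in TimeTree(node, validate=False).tips())
            counts[clade] = counts.get(clade, 0) + 1
    n = len(tree_samples)
    clade_pp = {c: cnt / n for c, cnt in counts.items()}
    tns = dendropy.TaxonNamespace()
    tlist = dendropy.TreeList(taxon_namespace=tns)
    for t in tree_samples:
        tlist.append(dendropy.Tree.get(data=t.to_newick(), schema="newick",
                                       taxon_namespace=tns,
                                       preserve_underscores=True))
    cons = tlist.consensus(min_freq=0.5)
    return ConsensusTree(cons, clade_pp)


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

@dataclass
class GridCell:
    """One analysis cell: a named model spec + run configuration."""

    name: str
    spec: "ModelSpec"
    config: "McmcConfig"
    use_fossils: bool = True


def _config_hash(spec, config) -> str:
    text = repr(spec) + repr(config)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_experiment_grid(data, cells: Sequence[GridCell],
                        clades: Mapping[str, Sequence[str]] | None = None,
                        kde_adjust: float = 3.0):
    """Run every grid cell and summarize.

    Returns (table, densities): one table row per cell with root-age and
    clade-age summaries, the posterior mean ghost-lineage excess and
    convergence flags; ``densities`` maps cell name -> (x, y) KDE of the
    root age for overlay plots.  A cell failing its convergence check is
    flagged and the grid continues.
    """
    from tedkit.mcmc import run_mc3, convergence_diagnostics, DataBundle

    rows = []
    densities = {}
    clade_tables = {}
    for cell in cells:
        bundle = data
        if not cell.use_fossils:
            tree = data.tree
            if tree is not None and tree.fossil_tips():
                tree = prune_fossils(tree)
            bundle = DataBundle(
                morph=(data.morph.subset_taxa(_extant_of(data))
                       if data.morph is not None else None),
                mol=(data.mol.subset_taxa(_extant_of(data))
                     if data.mol is not None else None),
                fossils=FossilTable({}), tree=tree)
        runs = run_mc3(cell.spec, bundle, cell.config)
        chash = _config_hash(cell.spec, cell.config)
        pooled = pd.concat([r.trace[~r.trace["burnin"]] for r in runs])
        trees = [t for r in runs
                 for t, b in zip(r.trees, r.trace["burnin"]) if not b]
        root_ages = pooled["root_age"].to_numpy()
        lo, hi = hpd(root_ages)
        row = {
            "cell": cell.name,
            "config_hash": chash,
            "seed": cell.config.seed,
            "root_age_median": float(np.median(root_ages)),
            "root_age_hpd_low": lo,
            "root_age_hpd_high": hi,
            "ghost_excess_mean": float(pooled["ghost_excess"].mean()),
            "n_samples": len(pooled),
        }
        if "youngest_split" in pooled.columns:
            row["youngest_split_median"] = float(
                np.median(pooled["youngest_split"]))
        if len(runs) >= 2:
            try:
                report = convergence_diagnostics(runs, params=["root_age"])
                row["psrf_root_age"] = report["psrf"]["root_age"]
                row["converged"] = not report["flags"]
            except Exception as exc:  # flagged, grid continues
                row["psrf_root_age"] = np.nan
                row["converged"] = False
        densities[cell.name] = kde(root_ages, kde_adjust)
        if clades:
            summary = summarize_clade_ages(trees, clades, chash,
                                           cell.config.seed)
            clade_tables[cell.name] = summary.table
            for cname in summary.table.index:
                row[f"{cname}_median"] = summary.table.loc[cname, "median"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("cell")
    return table, densities, clade_tables


def _extant_of(data) -> list[str]:
    fossil_names = set(data.fossils.ages) if data.fossils else set()
    taxa = data.morph.taxa if data.morph is not None else data.mol.taxa
    return [t for t in taxa if t not in fossil_names]
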