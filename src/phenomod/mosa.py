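"""Multi-objective simulated annealing for phenotype-specific modules.

The search looks for a gene set that is (1) large, (2) densely coexpressed
in the datasets where it is dense at all, (3) denser in datasets annotated
with the target phenotype than elsewhere, and (4) dense *specifically* in
the phenotype's datasets, as measured by an upper-tail hypergeometric test
on the overlap between the phenotype's dataset set and the module's dense
dataset set.

The four objectives are scalarized into a single energy (lower is better)
by a negative weighted sum of min-max-normalized objective values, with the
normalization extrema updated as the search runs.  A standard Metropolis
acceptance rule with geometric cooling drives the walk; moves add a gene
adjacent (in at least one phenotype network) to the current set, remove a
member, or swap.  Candidates from all restarts are post-filtered on size,
density, and a Benjamini-Hochberg-corrected specificity p-value.

All logarithms are natural logs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from phenomod.coexpression import CoexpressionNetwork, dense_dataset_set, module_density


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order-preserving)."""
    _, adj, _, _ = multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")
    return adj


def specificity_pvalue(
    n_total: int, n_pheno: int, n_dense: int, n_overlap: int
) -> float:
    """Upper-tail hypergeometric P(X >= n_overlap).

    ``n_dense`` datasets are drawn from a population of ``n_total`` of which
    ``n_pheno`` are annotated with the phenotype; ``n_overlap`` is the
    observed count of phenotype datasets among the dense ones.
    """
    if not (0 <= n_overlap <= min(n_pheno, n_dense) <= n_total):
        raise ValueError(
            f"inconsistent counts: total={n_total} pheno={n_pheno} "
            f"dense={n_dense} overlap={n_overlap}"
        )
    if n_pheno > n_total or n_dense > n_total:
        raise ValueError("group sizes exceed the population")
    return float(hypergeom.sf(n_overlap - 1, n_total, n_pheno, n_dense))


def density_differential(
    nets: Sequence[CoexpressionNetwork],
    genes: Iterable[str],
    pheno_dataset_ids: Iterable[str],
) -> float:
    """Mean module density in phenotype datasets minus mean elsewhere."""
    pheno_ids = set(pheno_dataset_ids)
    gene_set = set(genes)
    pheno = [n for n in nets if n.dataset_id in pheno_ids]
    background = [n for n in nets if n.dataset_id not in pheno_ids]
    if not pheno or not background:
        raise ValueError("both phenotype and background dataset groups must be non-empty")
    mean_p = float(np.mean([module_density(n, gene_set) for n in pheno]))
    mean_b = float(np.mean([module_density(n, gene_set) for n in background]))
    return mean_p - mean_b


@dataclass
class MOSAConfig:
    """Search and filter settings.

    ``weights`` scalarize (size, mean density over dense datasets, density
    differential, -log specificity p).  Cooling is geometric; the anneal
    stops when the temperature falls below ``t_min``.
    """

    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 2.0)
    t0: float = 1.0
    cooling: float = 0.9
    steps_per_temp: int = 200
    t_min: float = 1e-3
    restarts: int = 3
    tau_dense: float = 0.66
    seed: int = 0
    min_size: int = 7
    min_density: float = 0.66
    fdr_alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must lie in (0, 1)")
        if any(w < 0 for w in self.weights):
            raise ValueError("objective weights must be >= 0")
        if self.steps_per_temp < 1 or self.restarts < 1:
            raise ValueError("counts must be >= 1")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if not 0 < self.tau_dense <= 1:
            raise ValueError("tau_dense must be in (0, 1]")


@dataclass
class ModuleCandidate:
    """Best state of one annealing restart, before filtering."""

    genes: frozenset[str]
    phenotype: str | None
    dense_datasets: frozenset[str]
    objectives: tuple[float, float, float, float]  # size, density, differential, -log p
    specificity_p: float
    provenance: tuple[int, int]  # (seed, restart index)

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def mean_density(self) -> float:
        return self.objectives[1]


@dataclass
class PhenotypeModule:
    """A filtered, reportable phenotype-specific coexpression module."""

    module_id: str
    genes: frozenset[str]
    phenotype: str | None
    dense_datasets: frozenset[str]
    size: int
    mean_density: float
    density_differential: float
    specificity_p: float
    fdr_p: float


class ObjectiveExtrema:
    """Running min/max per objective for min-max normalization."""

    def __init__(self) -> None:
        self.lo = [math.inf] * 4
        self.hi = [-math.inf] * 4

    def update(self, objs: Sequence[float]) -> None:
        for i, v in enumerate(objs):
            if v < self.lo[i]:
                self.lo[i] = v
            if v > self.hi[i]:
                self.hi[i] = v

    def normalize(self, objs: Sequence[float]) -> tuple[float, ...]:
        out = []
        for i, v in enumerate(objs):
            span = self.hi[i] - self.lo[i]
            out.append((v - self.lo[i]) / span if span > 0 else 0.0)
        return tuple(out)


def energy(
    candidate: ModuleCandidate,
    config: MOSAConfig,
    extrema: ObjectiveExtrema | None = None,
) -> float:
    """Negative weighted sum of (normalized) objectives; lower is better.

    Without ``extrema``, raw objective values are used, which makes the
    energy an exact hand-checkable weighted sum.
    """
    objs = candidate.objectives
    vals = extrema.normalize(objs) if extrema is not None else objs
    return -sum(w * v for w, v in zip(config.weights, vals))


def _sf_table(n_total: int, n_pheno: int) -> np.ndarray:
    """tab[N, k] = P(X >= k) for X ~ Hypergeom(n_total, n_pheno, N)."""
    tab = np.ones((n_total + 1, n_pheno + 1))
    for N in range(n_total + 1):
        kmax = min(N, n_pheno)
        ks = np.arange(kmax + 1)
        tab[N, : kmax + 1] = hypergeom.sf(ks - 1, n_total, n_pheno, N)
        tab[N, kmax + 1:] = 0.0
    return tab


class _AnnealState:
    """Incrementally maintained module state over stacked adjacency tensors."""

    def __init__(
        self,
        A: np.ndarray,  # (D, n, n) bool
        pheno_mask: np.ndarray,  # (D,) bool
        tau_dense: float,
        sf_tab: np.ndarray,
    ) -> None:
        self.A = A
        self.pheno_mask = pheno_mask
        self.tau = tau_dense
        self.sf_tab = sf_tab
        self.D, self.n, _ = A.shape
        self.n_pheno = int(pheno_mask.sum())
        # Union adjacency over phenotype networks guides the add move.
        self.U = A[pheno_mask].any(axis=0)
        self.members: list[int] = []
        self.in_set = np.zeros(self.n, dtype=bool)
        self.counts = np.zeros(self.D, dtype=np.int64)

    def reset(self, g1: int, g2: int) -> None:
        self.members = [g1, g2]
        self.in_set[:] = False
        self.in_set[[g1, g2]] = True
        self.counts = self.A[:, g1, g2].astype(np.int64)

    def delta_add(self, g: int) -> np.ndarray:
        return self.A[:, g, self.members].sum(axis=1)

    def add(self, g: int, delta: np.ndarray) -> None:
        self.members.append(g)
        self.in_set[g] = True
        self.counts += delta

    def remove(self, g: int) -> None:
        self.members.remove(g)
        self.in_set[g] = False
        self.counts -= self.A[:, g, self.members].sum(axis=1)

    def objectives_for(self, counts: np.ndarray, k: int) -> tuple[
        tuple[float, float, float, float], float, np.ndarray
    ]:
        """(O1..O4), raw specificity p, dense-dataset mask for a state."""
        pairs = k * (k - 1) // 2
        dens = counts / pairs
        dense = counts >= self.tau * pairs - 1e-9
        n_dense = int(dense.sum())
        n_overlap = int((dense & self.pheno_mask).sum())
        p = float(self.sf_tab[n_dense, n_overlap])
        o2 = float(dens[dense].mean()) if n_dense else 0.0
        o3 = float(dens[self.pheno_mask].mean() - dens[~self.pheno_mask].mean())
        o4 = -math.log(p) if p > 0 else 745.0  # cap at -log(min double)
        # Size enters on a log scale so that growth from 3 to 10 genes is
        # worth as much as growth from 30 to 100; with a linear size
        # objective, min-max normalization over the walk's full range makes
        # module-scale size differences vanish against the other objectives.
        return (math.log(k), o2, o3, o4), p, dense


def mosa_search(
    nets: Sequence[CoexpressionNetwork],
    pheno_dataset_ids: Iterable[str],
    universe: Iterable[str],
    config: MOSAConfig,
    phenotype: str | None = None,
    _trace=None,
) -> list[ModuleCandidate]:
    """Run the annealing search; one best-energy candidate per restart.

    Reproducible given ``config.seed``; restarts use seeds derived from it.
    """
    pheno_ids = set(pheno_dataset_ids)
    order = sorted(set(universe))
    n = len(order)
    if n < config.min_size:
        raise ValueError("gene universe smaller than min_size")
    pheno_mask = np.array([net.dataset_id in pheno_ids for net in nets])
    if pheno_mask.sum() < 2 or (~pheno_mask).sum() < 1:
        raise ValueError(
            "need >= 2 phenotype datasets and >= 1 background dataset"
        )

    A = np.stack([net.adjacency(order) for net in nets])
    # Seed the walk at an edge that recurs across the phenotype's networks:
    # recurrently coexpressed pairs are far likelier to sit inside a
    # phenotype-specific module than any single network's edges.
    recurrence = np.triu(A[pheno_mask].sum(axis=0), k=1)
    if recurrence.max() == 0:
        warnings.warn(
            "phenotype networks have no edges; returning no candidates",
            stacklevel=2,
        )
        return []
    init_edges = np.argwhere(recurrence == recurrence.max())

    sf_tab = _sf_table(len(nets), int(pheno_mask.sum()))
    state = _AnnealState(A, pheno_mask, config.tau_dense, sf_tab)

    n_temps = max(1, math.ceil(math.log(config.t_min / config.t0) / math.log(config.cooling)))
    results: list[ModuleCandidate] = []

    for restart in range(config.restarts):
        rng = np.random.default_rng((config.seed, restart))
        extrema = ObjectiveExtrema()

        g1, g2 = init_edges[rng.integers(len(init_edges))]
        state.reset(int(g1), int(g2))

        objs, p_raw, dense = state.objectives_for(state.counts, 2)
        extrema.update(objs)
        cur_objs, cur_p, cur_dense = objs, p_raw, dense
        # Visited (accepted) states; the best is chosen under the final,
        # stabilized normalization, since early extrema are degenerate.
        history = [(frozenset(state.members), objs, p_raw, dense)]

        # Greedy expansion of the seed before annealing: a bare seed edge is
        # routinely destroyed during the hot phase, so the anneal starts
        # from the locally optimal module around the seed and refines it.
        while True:
            addable = state.U[:, state.members].any(axis=1) & ~state.in_set
            cand = []
            for g in np.flatnonzero(addable):
                d = state.delta_add(int(g))
                o, p, dn = state.objectives_for(state.counts + d, len(state.members) + 1)
                if dn.any():
                    extrema.update(o)
                    cand.append((int(g), d, o, p, dn))
            if not cand:
                break
            e_cur = -sum(
                w * v for w, v in zip(config.weights, extrema.normalize(cur_objs))
            )
            scored = [
                (
                    -sum(
                        w * v
                        for w, v in zip(config.weights, extrema.normalize(o))
                    ),
                    g,
                    d,
                    o,
                    p,
                    dn,
                )
                for g, d, o, p, dn in cand
            ]
            e_best, g, d, o, p, dn = min(scored, key=lambda t: (t[0], t[1]))
            if e_best >= e_cur - 1e-12:
                break
            state.add(g, d)
            cur_objs, cur_p, cur_dense = o, p, dn
            history.append((frozenset(state.members), o, p, dn))

        T = config.t0
        for _ in range(n_temps):
            for _ in range(config.steps_per_temp):
                k = len(state.members)
                addable = state.U[:, state.members].any(axis=1) & ~state.in_set
                add_idx = np.flatnonzero(addable)
                moves = []
                if len(add_idx):
                    moves.append("add")
                if k > 2:
                    moves.append("remove")
                if len(add_idx) and k > 2:
                    moves.append("swap")
                if not moves:
                    break
                move = moves[rng.integers(len(moves))]

                if move == "add":
                    g = int(add_idx[rng.integers(len(add_idx))])
                    delta = state.delta_add(g)
                    new_counts = state.counts + delta
                    new_k = k + 1
                    undo = ("add", g, delta)
                elif move == "remove":
                    g = state.members[rng.integers(k)]
                    delta = state.A[:, g, state.members].sum(axis=1) - state.A[:, g, g]
                    new_counts = state.counts - delta
                    new_k = k - 1
                    undo = ("remove", g, delta)
                else:  # swap = remove one member, add one outside gene
                    g_out = state.members[rng.integers(k)]
                    g_in = int(add_idx[rng.integers(len(add_idx))])
                    d_out = state.A[:, g_out, state.members].sum(axis=1)
                    d_in = state.A[:, g_in, state.members].sum(axis=1) - state.A[:, g_in, g_out]
                    new_counts = state.counts - d_out + d_in
                    new_k = k
                    undo = ("swap", g_out, g_in)

                new_objs, new_p, new_dense = state.objectives_for(new_counts, new_k)
                # Hard feasibility: a module must be dense in >= 1 dataset.
                # Without this the walk can drift into the no-density region
                # where size is the only live objective and growth ratchets.
                if not new_dense.any():
                    continue
                extrema.update(new_objs)
                e_cur = -sum(
                    w * v for w, v in zip(config.weights, extrema.normalize(cur_objs))
                )
                e_new = -sum(
                    w * v for w, v in zip(config.weights, extrema.normalize(new_objs))
                )
                delta_e = e_new - e_cur
                if delta_e <= 0 or rng.random() < math.exp(-delta_e / T):
                    if undo[0] == "add":
                        state.add(undo[1], undo[2])
                    elif undo[0] == "remove":
                        state.remove(undo[1])
                    else:
                        state.remove(undo[1])
                        state.add(undo[2], state.delta_add(undo[2]))
                    cur_objs, cur_p, cur_dense = new_objs, new_p, new_dense
                    history.append(
                        (frozenset(state.members), new_objs, new_p, new_dense)
                    )
                    if _trace is not None:
                        _trace(restart, T, state.members)
            T *= config.cooling
            if T < config.t_min:
                break

        best = min(
            history,
            key=lambda h: -sum(
                w * v for w, v in zip(config.weights, extrema.normalize(h[1]))
            ),
        )
        genes = frozenset(order[i] for i in best[0])
        dense_ids = frozenset(
            nets[d].dataset_id for d in np.flatnonzero(best[3])
        )
        results.append(
            ModuleCandidate(
                genes=genes,
                phenotype=phenotype,
                dense_datasets=dense_ids,
                objectives=best[1],
                specificity_p=best[2],
                provenance=(config.seed, restart),
            )
        )
    return results


def filter_modules(
    candidates: Sequence[ModuleCandidate], config: MOSAConfig
) -> list[PhenotypeModule]:
    """Apply the size / density / BH-FDR specificity filters.

    Candidates below ``min_size`` or whose mean density over their dense
    datasets is below ``min_density`` are dropped first; Benjamini-Hochberg
    runs across the survivors' specificity p-values; exact duplicate gene
    sets are collapsed (lowest raw p wins).
    """
    survivors = [
        c
        for c in candidates
        if c.size >= config.min_size and c.mean_density >= config.min_density
    ]
    if not survivors:
        return []
    p_adj = bh_adjust([c.specificity_p for c in survivors])
    kept: dict[frozenset[str], tuple[ModuleCandidate, float]] = {}
    for cand, adj in zip(survivors, p_adj):
        if adj >= config.fdr_alpha:
            continue
        prev = kept.get(cand.genes)
        if prev is None or cand.specificity_p < prev[0].specificity_p:
            kept[cand.genes] = (cand, float(adj))
    modules = []
    ordered = sorted(
        kept.values(), key=lambda t: (t[0].specificity_p, sorted(t[0].genes))
    )
    for i, (cand, adj) in enumerate(ordered, start=1):
        label = cand.phenotype or "NA"
        modules.append(
            PhenotypeModule(
                module_id=f"{label}_m{i}",
                genes=cand.genes,
                phenotype=cand.phenotype,
                dense_datasets=cand.dense_datasets,
                size=cand.size,
                mean_density=cand.objectives[1],
                density_differential=cand.objectives[2],
                specificity_p=cand.specificity_p,
                fdr_p=adj,
            )
        )
    return modules


def write_modules(
    modules: Sequence[PhenotypeModule], gmt_path: str | Path, stats_path: str | Path
) -> None:
    """GMT-style gene-set file plus a per-module stats TSV."""
    gmt_lines = [
        "\t".join([m.module_id, m.phenotype or "NA", *sorted(m.genes)])
        for m in modules
    ]
    Path(gmt_path).write_text("\n".join(gmt_lines) + ("\n" if gmt_lines else ""))
    header = (
        "module_id\tphenotype\tsize\tmean_density\tdensity_differential\t"
        "specificity_p\tfdr_p\tdense_datasets"
    )
    rows = [
        f"{m.module_id}\t{m.phenotype or 'NA'}\t{m.size}\t{m.mean_density:.6g}\t"
        f"{m.density_differential:.6g}\t{m.specificity_p:.6g}\t{m.fdr_p:.6g}\t"
        f"{';'.join(sorted(m.dense_datasets))}"
        for m in modules
    ]
    Path(stats_path).write_text("\n".join([header, *rows]) + "\n")


def read_modules(
    gmt_path: str | Path, stats_path: str | Path | None = None
) -> list[PhenotypeModule]:
    stats: dict[str, dict[str, str]] = {}
    if stats_path is not None:
        lines = Path(stats_path).read_text().splitlines()
        cols = lines[0].split("\t")
        for line in lines[1:]:
            rec = dict(zip(cols, line.split("\t")))
            stats[rec["module_id"]] = rec
    modules = []
    for line in Path(gmt_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        mid, pheno, genes = parts[0], parts[1], frozenset(parts[2:])
        rec = stats.get(mid, {})
        modules.append(
            PhenotypeModule(
                module_id=mid,
                genes=genes,
                phenotype=None if pheno == "NA" else pheno,
                dense_datasets=frozenset(
                    x for x in rec.get("dense_datasets", "").split(";") if x
                ),
                size=len(genes),
                mean_density=float(rec.get("mean_density", "nan")),
                density_differential=float(rec.get("density_differential", "nan")),
                specificity_p=float(rec.get("specificity_p", "nan")),
                fdr_p=float(rec.get("fdr_p", "nan")),
            )
        )
    return modules
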