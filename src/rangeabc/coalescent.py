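"""Backward coalescent through a recorded demography, with SMM mutation.

Sampled gene lineages are traced backward generation by generation through
the :class:`~rangeabc.forward.DemographyRecord`: a lineage in deme *d* was,
one generation earlier, in source *s* with probability ``immigrants(s->d) /
N(d)`` and stayed put with the residual mass.  Lineages co-resident in a
deme of haploid size ``N`` coalesce pairwise with probability
``k(k-1)/(2N)`` (at most one merger per deme per generation — an
approximation, adequate while deme sizes far exceed co-resident lineage
counts).  Lineages that survive to the start of the expansion coalesce in
the ancestral origin deme of ``2*Ne_ANC`` genes under the standard
continuous-time coalescent.

Microsatellite alleles evolve under a strict stepwise mutation model:
``Poisson(rate * branch length)`` mutations per branch, each changing the
repeat count by +-1 with equal probability.  The root repeat count is an
arbitrary translation anchor (30) — every downstream statistic is
translation invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import DemographyRecord

ROOT_REPEAT = 30
MISSING = -9


class RecordConsistencyError(RuntimeError):
    """The demography record contradicts itself (or the sampling design)."""


@dataclass(frozen=True)
class SamplingDesign:
    """Which demes are sampled, how many diploids each, and locus count."""

    sites: tuple  # of (label, (row, col), n_diploid, group)
    n_loci: int = 50

    @classmethod
    def from_landscape(cls, landscape, n_loci: int = 50) -> "SamplingDesign":
        return cls(
            tuple((s.label, (s.row, s.col), s.n_diploid, s.group) for s in landscape.samples),
            n_loci,
        )

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.sites]

    @property
    def groups(self) -> dict[str, str]:
        return {s[0]: s[3] for s in self.sites}

    @property
    def n_genes(self) -> int:
        return int(sum(2 * s[2] for s in self.sites))

    def validate_against(self, record: DemographyRecord) -> None:
        present = record.densities[-1]
        for label, (r, c), n, _ in self.sites:
            if n < 1:
                raise ValueError(f"sample {label!r}: size must be >= 1")
            if present[r, c] < 2 * n:
                raise RecordConsistencyError(
                    f"sampled deme {label!r} at ({r},{c}) holds {present[r, c]:.0f} genes "
                    f"at present, fewer than the {2 * n} sampled"
                )


@dataclass
class Tree:
    """One genealogy: binary, leaves 0..n_leaves-1 at time 0, times in
    generations before present, ``parent[root] == -1``."""

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def tmrca(self) -> float:
        return float(self.time.max())


# ---------------------------------------------------------------------------
# backward movement kernel
# ---------------------------------------------------------------------------


def backward_move(record: DemographyRecord, deme: tuple[int, int], t: int):
    """Source distribution for a lineage in ``deme`` at ``t`` generations BP.

    Returns ``(sources, probs)`` where sources are deme coordinates one
    generation earlier (backward); the lineage's own deme carries the
    residual stay probability.
    """
    T = record.n_steps
    tau = T - t
    if not (1 <= tau <= T):
        raise ValueError(f"t={t} outside the recorded span")
    r, c = deme
    n_here = float(record.densities[tau, r, c])
    if n_here <= 0:
        raise RecordConsistencyError(f"deme ({r},{c}) queried at t={t} has zero density")
    from .forward import DIRS

    sources, probs = [], []
    arr = record.adj_arrivals[tau - 1]
    for d, (dr, dc) in enumerate(DIRS):
        cnt = float(arr[d, r, c])
        if cnt > 0:
            sources.append((r + dr, c + dc))
            probs.append(cnt / n_here)
    ldd = record.ldd_arrivals[tau - 1]
    if ldd is not None:
        here = r * record.landscape.n_cols + c
        for tgt, src, cnt in ldd:
            if tgt == here:
                sources.append((int(src) // record.landscape.n_cols, int(src) % record.landscape.n_cols))
                probs.append(float(cnt) / n_here)
    stay = 1.0 - sum(probs)
    if stay < -1e-6:
        raise RecordConsistencyError(
            f"immigrants into ({r},{c}) at t={t} exceed its recorded density"
        )
    sources.append((r, c))
    probs.append(max(stay, 0.0))
    return sources, np.asarray(probs)


# ---------------------------------------------------------------------------
# genealogy simulation (batched over loci)
# ---------------------------------------------------------------------------


def _simulate_forest(record: DemographyRecord, design: SamplingDesign, rng, n_loci: int):
    """Simulate ``n_loci`` independent genealogies in one backward sweep.

    Returns ``(parents, times, n_leaves)`` with per-locus node arrays of
    length ``2*n_leaves - 1`` (leaves first, then internal nodes in
    coalescence order).
    """
    design.validate_against(record)
    lsc = record.landscape
    R, C = lsc.shape
    T = record.n_steps
    L = design.n_genes
    n_nodes = 2 * L - 1

    leaf_demes = np.concatenate(
        [np.full(2 * n, r * C + c, dtype=np.int64) for _, (r, c), n, _ in design.sites]
    )
    parents = np.full((n_loci, n_nodes), -1, dtype=np.int32)
    times = np.zeros((n_loci, n_nodes), dtype=np.float64)
    next_node = np.full(n_loci, L, dtype=np.int32)

    # active lineage state, flattened over loci
    lin_deme = np.tile(leaf_demes, n_loci)
    lin_locus = np.repeat(np.arange(n_loci, dtype=np.int64), L)
    lin_node = np.tile(np.arange(L, dtype=np.int32), n_loci)
    alive_per_locus = np.full(n_loci, L, dtype=np.int64)

    dens = record.densities

    for g in range(1, T + 1):
        if len(lin_deme) == 0:
            break
        tau_from = T - g + 1
        tau_to = T - g

        n_from = dens[tau_from].ravel()[lin_deme].astype(np.float64)
        if np.any(n_from <= 0):
            bad = lin_deme[n_from <= 0][0]
            raise RecordConsistencyError(
                f"lineage stranded in unoccupied deme ({bad // C},{bad % C}) "
                f"{g - 1} generations BP"
            )
        arr = record.adj_arrivals[tau_to]  # (4, R, C) transition tau_to -> tau_from
        a = arr.reshape(4, -1)[:, lin_deme].astype(np.float64)  # (4, L)
        p = a / n_from  # per-direction move probabilities
        cum = np.cumsum(p, axis=0)
        u = rng.random(len(lin_deme))
        choice = (u[None, :] < cum).sum(axis=0)  # 4 - (#dirs passed); 0 => beyond all
        moved_dir = 4 - choice  # dir index if < 4 else stay
        new_deme = lin_deme.copy()
        from .forward import DIRS

        for d, (dr, dc) in enumerate(DIRS):
            sel = moved_dir == d
            if sel.any():
                new_deme[sel] = lin_deme[sel] + dr * C + dc

        # long-distance arrivals occupy the probability band above the
        # adjacent ones: u in [cum_adj, cum_adj + p_ldd).  Rows are sorted
        # by target deme, so a cumulative-count search resolves the source.
        ldd = record.ldd_arrivals[tau_to]
        if ldd is not None and len(ldd):
            tgts = ldd[:, 0].astype(np.int64)
            cnts = ldd[:, 2].astype(np.float64)
            csum = np.cumsum(cnts)
            stay = moved_dir >= 4
            if stay.any():
                idxs = np.flatnonzero(stay)
                d_here = lin_deme[idxs]
                lo = np.searchsorted(tgts, d_here, side="left")
                hi = np.searchsorted(tgts, d_here, side="right")
                has = hi > lo
                if has.any():
                    idxs = idxs[has]
                    lo, hi = lo[has], hi[has]
                    base = np.where(lo > 0, csum[lo - 1], 0.0)
                    total = csum[hi - 1] - base
                    # residual uniform above the adjacent band, scaled to genes
                    v = (u[idxs] - cum[3, idxs]) * n_from[idxs]
                    is_ldd = v < total
                    if is_ldd.any():
                        j = np.searchsorted(csum, base[is_ldd] + v[is_ldd], side="right")
                        new_deme[idxs[is_ldd]] = ldd[j, 1]
        lin_deme = new_deme

        # ---- coalescence within (locus, deme) groups ----
        if tau_to > 0:
            n_to = dens[tau_to].ravel()
        else:
            n_to = dens[0].ravel()
        key = lin_locus * (R * C) + lin_deme
        order = np.argsort(key, kind="stable")
        sk = key[order]
        starts = np.flatnonzero(np.concatenate(([True], sk[1:] != sk[:-1])))
        counts = np.diff(np.concatenate((starts, [len(sk)])))
        multi = counts >= 2
        if multi.any():
            g_starts = starts[multi]
            g_counts = counts[multi]
            g_demes = lin_deme[order[g_starts]]
            nn = np.maximum(n_to[g_demes], 1.0)
            p_coal = np.minimum(1.0, g_counts * (g_counts - 1) / 2.0 / nn)
            do = rng.random(len(p_coal)) < p_coal
            if do.any():
                drop = np.zeros(len(lin_deme), dtype=bool)
                for s0, k in zip(g_starts[do], g_counts[do]):
                    members = order[s0 : s0 + k]
                    pair = rng.choice(k, size=2, replace=False)
                    i, j = members[pair[0]], members[pair[1]]
                    loc = lin_locus[i]
                    node = next_node[loc]
                    next_node[loc] += 1
                    parents[loc, lin_node[i]] = node
                    parents[loc, lin_node[j]] = node
                    times[loc, node] = g
                    lin_node[i] = node
                    drop[j] = True
                    alive_per_locus[loc] -= 1
                keep = ~drop
                lin_deme = lin_deme[keep]
                lin_locus = lin_locus[keep]
                lin_node = lin_node[keep]
        # retire finished loci
        done = alive_per_locus[lin_locus] <= 1
        if done.any():
            keep = ~done
            lin_deme = lin_deme[keep]
            lin_locus = lin_locus[keep]
            lin_node = lin_node[keep]

    # ---- ancestral panmictic phase (continuous-time Kingman) ----
    if len(lin_deme):
        two_ne = 2.0 * record.params.Ne_ANC
        for loc in np.unique(lin_locus):
            sel = lin_locus == loc
            nodes = list(lin_node[sel])
            t_now = float(T)
            while len(nodes) > 1:
                k = len(nodes)
                t_now += rng.exponential(two_ne / (k * (k - 1) / 2.0))
                i, j = rng.choice(k, size=2, replace=False)
                node = next_node[loc]
                next_node[loc] += 1
                parents[loc, nodes[i]] = node
                parents[loc, nodes[j]] = node
                times[loc, node] = t_now
                nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [node]
    return parents, times, L


def simulate_genealogy(record: DemographyRecord, design: SamplingDesign, rng) -> Tree:
    """One genealogy of all sampled genes through the recorded demography."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    parents, times, L = _simulate_forest(record, design, rng, n_loci=1)
    return Tree(parents[0], times[0], L)


# ---------------------------------------------------------------------------
# stepwise mutation model
# ---------------------------------------------------------------------------


def mutate_smm(tree: Tree, mutation_rate: float, root_repeat: int = ROOT_REPEAT, rng=None):
    """Drop SMM mutations on a genealogy; return leaf repeat counts."""
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if mutation_rate < 0:
        raise ValueError("mutation rate must be >= 0")
    vals = _mutate_forest(
        tree.parent[None, :], tree.time[None, :], tree.n_leaves, mutation_rate, root_repeat, rng
    )
    return vals[0]


def _mutate_forest(parents, times, n_leaves, rate, root_repeat, rng):
    n_loci, n_nodes = parents.shape
    bl = np.zeros_like(times)
    has_p = parents >= 0
    bl[has_p] = np.take_along_axis(times, np.where(has_p, parents, 0), axis=1)[has_p] - times[has_p]
    nmut = rng.poisson(rate * bl)
    # net displacement of a +-1 random walk with nmut steps
    up = rng.binomial(nmut, 0.5)
    delta = 2 * up - nmut
    vals = np.full((n_loci, n_nodes), root_repeat, dtype=np.int64)
    # parents always have larger node index than children here, so a single
    # reverse sweep propagates root -> leaves
    for j in range(n_nodes - 2, -1, -1):
        p = parents[:, j]
        ok = p >= 0
        vals[ok, j] = vals[ok, p[ok]] + delta[ok, j]
    leaves = vals[:, :n_leaves]
    below = leaves < 1
    if below.any():  # reflecting boundary at one repeat
        leaves[below] = 2 - leaves[below]
    return leaves


# ---------------------------------------------------------------------------
# genotype container and dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """Population-structured repeat-count genotypes at unlinked loci.

    ``genotypes[pop]`` has shape ``(n_individuals, n_loci, 2)`` with
    integer repeat counts, ``-9`` marking missing alleles.
    """

    populations: list[str]
    groups: dict[str, str]
    locus_names: list[str]
    genotypes: dict[str, np.ndarray]

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def n_individuals(self, pop: str) -> int:
        return self.genotypes[pop].shape[0]

    def genes(self, pop: str, locus_index: int) -> np.ndarray:
        """Non-missing gene copies of one population at one locus."""
        g = self.genotypes[pop][:, locus_index, :].ravel()
        return g[g != MISSING]

    def subset_loci(self, indices) -> "GenotypeDataset":
        indices = np.asarray(indices)
        return GenotypeDataset(
            list(self.populations),
            dict(self.groups),
            [self.locus_names[i] for i in indices],
            {p: g[:, indices, :].copy() for p, g in self.genotypes.items()},
        )

    def inject_missing(self, rate: float, rng) -> "GenotypeDataset":
        """Set alleles missing completely at random at the given rate."""
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        out = {}
        for p, g in self.genotypes.items():
            g = g.copy()
            mask = rng.random(g.shape) < rate
            g[mask] = MISSING
            out[p] = g
        return GenotypeDataset(list(self.populations), dict(self.groups), list(self.locus_names), out)

    # -- I/O ---------------------------------------------------------------

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for pop in self.populations:
            g = self.genotypes[pop]
            for i in range(g.shape[0]):
                for j, locus in enumerate(self.locus_names):
                    rows.append((pop, f"{pop}_{i:03d}", locus, int(g[i, j, 0]), int(g[i, j, 1])))
        return pd.DataFrame(rows, columns=["pop", "indiv", "locus", "allele1", "allele2"])

    def write_tsv(self, path) -> None:
        self.to_long_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, groups: dict[str, str]) -> "GenotypeDataset":
        df = pd.read_csv(path, sep="\t")
        loci = sorted(df["locus"].unique())
        loc_idx = {l: j for j, l in enumerate(loci)}
        pops = list(dict.fromkeys(df["pop"]))
        geno = {}
        for pop, sub in df.groupby("pop", sort=False):
            inds = list(dict.fromkeys(sub["indiv"]))
            ind_idx = {x: i for i, x in enumerate(inds)}
            g = np.full((len(inds), len(loci), 2), MISSING, dtype=np.int64)
            g[sub["indiv"].map(ind_idx), sub["locus"].map(loc_idx), 0] = sub["allele1"]
            g[sub["indiv"].map(ind_idx), sub["locus"].map(loc_idx), 1] = sub["allele2"]
            geno[pop] = g
        return cls(pops, groups, loci, geno)

    def write_structure(self, path) -> None:
        """STRUCTURE format: two rows per individual, one column per locus."""
        with open(path, "w") as fh:
            fh.write("\t".join(["indiv", "pop"] + list(self.locus_names)) + "\n")
            for pi, pop in enumerate(self.populations, start=1):
                g = self.genotypes[pop]
                for i in range(g.shape[0]):
                    for a in (0, 1):
                        cells = [f"{pop}_{i:03d}", str(pi)] + [str(int(x)) for x in g[i, :, a]]
                        fh.write("\t".join(cells) + "\n")


def simulate_dataset(
    record: DemographyRecord,
    design: SamplingDesign,
    mutation_rate: float,
    seed,
) -> GenotypeDataset:
    """Simulate a full multilocus dataset: independent genealogies per
    locus, SMM mutation, genotypes assembled per diploid individual.
    Deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_loci = design.n_loci
    locus_names = [f"L{j:03d}" for j in range(n_loci)]
    pops = design.labels
    if n_loci == 0:
        geno = {
            label: np.empty((n, 0, 2), dtype=np.int64)
            for label, _, n, _ in design.sites
        }
        return GenotypeDataset(pops, design.groups, locus_names, geno)

    parents, times, L = _simulate_forest(record, design, rng, n_loci)
    leaves = _mutate_forest(parents, times, L, mutation_rate, ROOT_REPEAT, rng)  # (n_loci, L)
    geno = {}
    offset = 0
    for label, _, n, _ in design.sites:
        block = leaves[:, offset : offset + 2 * n]  # (n_loci, 2n)
        geno[label] = np.ascontiguousarray(
            block.T.reshape(n, 2, n_loci).transpose(0, 2, 1)
        ).astype(np.int64)
        offset += 2 * n
    return GenotypeDataset(pops, design.groups, locus_names, geno)
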