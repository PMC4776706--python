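"""Forward-in-time lattice demography with long-distance dispersal.

One simulation runs from the start of the expansion (``T_STARTEXP``
generations BP, a single occupied origin deme of ``2*Ne_ANC`` genes) to the
present.  Each generation applies, in order: carrying-capacity update
(corridor opening, glacial contraction, Neolithic increase), logistic
growth, emigration (nearest-neighbour plus long-distance dispersal), and
immigrant deposition.  Densities are real-valued haploid gene counts;
migrant counts are integer random variates — deterministic growth with
stochastic migration.  Everything the backward coalescent needs (per-step
densities and immigrant counts by source, split into adjacent and LDD
entries) is recorded.

Long-distance dispersal (LDD): of the ``M = round(2*N_t*m)`` emigrant genes
of a deme, ``Binomial(M, LDD_PROP)`` are long-distance dispersers.  Each
travels ``x`` demes, ``x ~ Gamma(shape=alpha, rate=alpha/mu_bar)`` rounded
to the nearest integer and resampled until it lies in [2, 6] (LDD is by
definition non-adjacent, and is capped at 6 demes), in a uniform random
direction.  A disperser whose target is sea, barrier, out of the grid,
currently uninhabitable, or disallowed by the regime (``empty_only`` /
``occupied_only``) is lost; losses are counted in the diagnostics.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict

import numpy as np

from .landscape import (
    ContractionSchedule,
    Landscape,
    T_NEOLITHIC,
    capacity_at,
)

#: neighbour offsets; direction d means "source deme = target + DIRS[d]"
DIRS = ((-1, 0), (1, 0), (0, -1), (0, 1))

LDD_MIN_DEMES = 2
LDD_MAX_DEMES = 6


@dataclass(frozen=True)
class ScenarioSpec:
    """Model flags: LDD regime, glacial range contraction, Neolithic growth."""

    ldd_regime: str = "none"  # none | any | empty_only | occupied_only
    range_contraction: bool = False
    neolithic: bool = False
    deme_side_km: float = 150.0
    t_neolithic: int = T_NEOLITHIC

    def __post_init__(self):
        if self.ldd_regime not in ("none", "any", "empty_only", "occupied_only"):
            raise ValueError(f"unknown LDD regime {self.ldd_regime!r}")

    @property
    def has_ldd(self) -> bool:
        return self.ldd_regime != "none"


#: the named models, 1:1 with flag combinations
SCENARIOS: dict[str, ScenarioSpec] = {
    "noLDDnoRC": ScenarioSpec("none", False),
    "noLDDRC": ScenarioSpec("none", True),
    "LDDnoRC": ScenarioSpec("any", False),
    "LDDRC": ScenarioSpec("any", True),
    "LDDnoRCep": ScenarioSpec("empty_only", False),
    "LDDnoRCop": ScenarioSpec("occupied_only", False),
    "LDDRCep": ScenarioSpec("empty_only", True),
    "LDDRCop": ScenarioSpec("occupied_only", True),
    "noLDDRCKNeo": ScenarioSpec("none", True, neolithic=True),
}


@dataclass
class ParamVector:
    """Numeric model parameters (times in generations BP, sizes diploid)."""

    T_STARTEXP: int
    T_OOA: int
    Ne_ANC: float
    K: float
    r: float
    m: float
    LDD_PROP: float = 0.0
    mu_bar: float = 0.0
    alpha: float = 0.0
    STR_MUTRATE: float = 1.5e-4
    KNeo: float = 0.0

    def __post_init__(self):
        if not self.T_STARTEXP > self.T_OOA > 0:
            raise ValueError("need T_STARTEXP > T_OOA > 0")
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.LDD_PROP <= 1.0):
            raise ValueError("m and LDD_PROP must lie in [0, 1]")
        if self.mu_bar > LDD_MAX_DEMES:
            raise ValueError("mu_bar cannot exceed the 6-deme LDD cap")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Diagnostics:
    emigrants: float = 0.0
    arrivals: float = 0.0
    lost_at_sea: float = 0.0
    ldd_sent: float = 0.0
    ldd_arrived: float = 0.0
    ldd_discarded: float = 0.0


class DemographyRecord:
    """The forward→backward contract.

    ``densities[tau]`` is the haploid gene-count grid after ``tau``
    generations of the simulation (``tau = 0`` at ``T_STARTEXP`` BP,
    ``tau = T_STARTEXP`` at present).  ``adj_arrivals[tau]`` holds, for the
    transition ``tau -> tau+1``, the genes arriving into each deme from its
    four neighbours; ``ldd_arrivals[tau]`` is a sparse ``(target, source,
    count)`` integer array for long-distance arrivals of the same
    transition.
    """

    def __init__(self, landscape, scenario, params, densities, adj_arrivals, ldd_arrivals, diagnostics, extinct=False):
        self.landscape = landscape
        self.scenario = scenario
        self.params = params
        self.densities = densities
        self.adj_arrivals = adj_arrivals
        self.ldd_arrivals = ldd_arrivals
        self.diagnostics = diagnostics
        self.extinct = extinct

    @property
    def n_steps(self) -> int:
        return self.densities.shape[0] - 1

    def density_at_present(self) -> np.ndarray:
        return self.densities[-1]

    def occupied_at_present(self) -> np.ndarray:
        return self.densities[-1] >= 1.0

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write a compressed columnar archive; round-trips bit-exact."""
        steps, tgts, srcs, cnts = [], [], [], []
        for tau, arr in enumerate(self.ldd_arrivals):
            if arr is not None and len(arr):
                steps.append(np.full(len(arr), tau, dtype=np.int32))
                tgts.append(arr[:, 0])
                srcs.append(arr[:, 1])
                cnts.append(arr[:, 2])
        cat = (lambda xs: np.concatenate(xs) if xs else np.empty(0, dtype=np.int32))
        meta = json.dumps(
            {
                "scenario": asdict(self.scenario),
                "params": self.params.to_dict(),
                "extinct": self.extinct,
                "diagnostics": asdict(self.diagnostics),
            }
        )
        np.savez_compressed(
            path,
            densities=self.densities,
            adj_arrivals=self.adj_arrivals,
            ldd_step=cat(steps),
            ldd_tgt=cat(tgts),
            ldd_src=cat(srcs),
            ldd_cnt=cat(cnts),
            meta=np.frombuffer(meta.encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path, landscape) -> "DemographyRecord":
        z = np.load(path)
        meta = json.loads(bytes(z["meta"]).decode())
        n_steps = z["densities"].shape[0] - 1
        ldd = [None] * n_steps
        step = z["ldd_step"]
        for tau in np.unique(step):
            sel = step == tau
            ldd[int(tau)] = np.column_stack(
                [z["ldd_tgt"][sel], z["ldd_src"][sel], z["ldd_cnt"][sel]]
            ).astype(np.int32)
        return cls(
            landscape,
            ScenarioSpec(**meta["scenario"]),
            ParamVector(**meta["params"]),
            z["densities"],
            z["adj_arrivals"],
            ldd,
            Diagnostics(**meta["diagnostics"]),
            extinct=meta["extinct"],
        )


# ---------------------------------------------------------------------------
# Elementary operations (scalar contracts; the driver uses vector forms)
# ---------------------------------------------------------------------------


def logistic_update(n, r, k):
    """One generation of logistic regulation: N + r*N*(1 - N/K).

    Works elementwise on arrays.  Demes with zero capacity go extinct.  A
    deme above capacity (e.g. the origin at expansion onset, seeded with
    2*Ne_ANC genes) declines but never below K — the discrete logistic
    would otherwise overshoot to negative densities.
    """
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(k > 0, n + r * n * (1.0 - n / np.where(k > 0, k, 1.0)), 0.0)
        out = np.where((k > 0) & (n > k), np.maximum(out, k), out)
    return out if out.ndim else float(out)


def emigrate(n_t, m, ldd_prop, rng):
    """Draw one deme's emigrant pool: LDD count and four neighbour counts.

    The pool is ``M = round(2*N_t*m)`` gene copies; ``Binomial(M,
    LDD_PROP)`` of them are long-distance dispersers, the rest are split by
    an equal-probability multinomial over the four directions (genes aimed
    at sea or barrier are lost by the caller).
    """
    M = int(np.rint(2.0 * n_t * m))
    M = min(M, int(n_t))
    ldd = int(rng.binomial(M, ldd_prop)) if ldd_prop > 0 else 0
    adj = rng.multinomial(M - ldd, [0.25] * 4)
    return ldd, adj


def _sample_ldd_distances(n, alpha, mu_bar, rng, max_iter=50):
    """n gamma-kernel distances, rounded, resampled into [2, 6].

    Oversamples in chunks so the rejection loop rarely runs twice.
    """
    scale = mu_bar / alpha
    chunks: list[np.ndarray] = []
    have = 0
    for it in range(max_iter):
        k = max(2 * (n - have) + 8, 16)
        x = np.rint(rng.gamma(alpha, scale, size=k)).astype(np.int64)
        x = x[(x >= LDD_MIN_DEMES) & (x <= LDD_MAX_DEMES)]
        if len(x):
            chunks.append(x[: n - have])
            have += len(chunks[-1])
        if have >= n:
            break
    if have < n:  # pathological kernel; fall back to the nearest bound
        chunks.append(np.full(n - have, LDD_MIN_DEMES, dtype=np.int64))
    return np.concatenate(chunks) if len(chunks) != 1 else chunks[0]


def sample_ldd_target(source, alpha, mu_bar, landscape, occupancy, regime, rng, habitable=None):
    """One LDD migrant's landing deme, or None if the gene is discarded.

    Distance from the truncated-rounded gamma kernel, direction uniform on
    the circle; the target is rounded to the lattice.  Discard (a normal
    outcome) happens when the target is off-grid, not habitable, or
    violates the ``empty_only`` / ``occupied_only`` regime.
    """
    if regime not in ("any", "empty_only", "occupied_only"):
        raise ValueError(f"invalid LDD regime {regime!r}")
    x = _sample_ldd_distances(1, alpha, mu_bar, rng)[0]
    theta = rng.uniform(0.0, 2.0 * np.pi)
    r = int(np.rint(source[0] + x * np.sin(theta)))
    c = int(np.rint(source[1] + x * np.cos(theta)))
    if not (0 <= r < landscape.n_rows and 0 <= c < landscape.n_cols):
        return None
    if habitable is None:
        habitable = landscape.habitable_after_ooa
    if not habitable[r, c]:
        return None
    if regime == "empty_only" and occupancy[r, c]:
        return None
    if regime == "occupied_only" and not occupancy[r, c]:
        return None
    return (r, c)


# ---------------------------------------------------------------------------
# The driver
# ---------------------------------------------------------------------------


def run_forward(
    landscape: Landscape,
    scenario: ScenarioSpec,
    params: ParamVector,
    seed,
    schedule: ContractionSchedule | None = None,
) -> DemographyRecord:
    """Run one forward demographic simulation and record it fully.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  Whole-
    metapopulation extinction before the present is flagged on the record
    (``extinct=True``), not raised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scenario.range_contraction and schedule is None:
        schedule = ContractionSchedule()
    if scenario.neolithic and params.KNeo <= 0:
        raise ValueError("Neolithic scenario requires KNeo > 0")

    T = int(params.T_STARTEXP)
    R, C = landscape.shape
    ncell = R * C
    densities = np.zeros((T + 1, R, C), dtype=np.float32)
    adj_arrivals = np.zeros((T, 4, R, C), dtype=np.int32)
    ldd_arrivals: list = [None] * T
    diag = Diagnostics()

    orow, ocol = landscape.origin
    densities[0, orow, ocol] = 2.0 * params.Ne_ANC

    # capacity is piecewise constant: recompute only at breakpoints
    breakpoints = {T - 1, int(params.T_OOA)}
    if scenario.range_contraction:
        breakpoints |= set(int(t) for t in schedule.event_times())
        breakpoints |= {schedule.t_end_gen, schedule.t_release_gen}
    if scenario.neolithic:
        breakpoints.add(scenario.t_neolithic - 1)
    k_genes = None

    ldd_active = scenario.has_ldd and params.LDD_PROP > 0
    flat = np.arange(ncell).reshape(R, C)

    for tau in range(T):
        t_bp = T - (tau + 1)  # time BP of the *new* state
        if k_genes is None or t_bp in breakpoints:
            k_genes = 2.0 * capacity_at(landscape, schedule, scenario, params, t_bp)
        n = densities[tau].astype(np.float64)
        grown = logistic_update(n, params.r, k_genes)

        occ_idx = np.flatnonzero(grown.ravel() >= 1.0)
        if len(occ_idx) == 0:
            return DemographyRecord(
                landscape, scenario, params, densities[: tau + 2],
                adj_arrivals[: tau + 1], ldd_arrivals[: tau + 1], diag, extinct=True,
            )
        pool = np.rint(2.0 * n.ravel()[occ_idx] * params.m).astype(np.int64)
        pool = np.minimum(pool, np.floor(grown.ravel()[occ_idx]).astype(np.int64))
        if ldd_active:
            ldd_counts = rng.binomial(pool, params.LDD_PROP)
        else:
            ldd_counts = np.zeros_like(pool)
        adj_counts = rng.multinomial(pool - ldd_counts, [0.25] * 4)  # (k, 4)

        emig = np.zeros(ncell, dtype=np.float64)
        emig[occ_idx] = pool
        diag.emigrants += float(pool.sum())

        habitable = k_genes > 0
        arrivals = np.zeros((4, R, C), dtype=np.int64)
        sent = np.zeros((R, C), dtype=np.int64)
        sr = occ_idx // C
        sc = occ_idx % C
        for d, (dr, dc) in enumerate(DIRS):
            # direction d records arrivals whose source is target+DIRS[d];
            # a gene sent from (sr,sc) toward (-dr,-dc) lands at target.
            tr = sr - dr
            tc = sc - dc
            ok = (tr >= 0) & (tr < R) & (tc >= 0) & (tc < C)
            cnt = adj_counts[:, d]
            sent[sr, sc] += cnt
            valid = ok.copy()
            valid[ok] &= habitable[tr[ok], tc[ok]]
            np.add.at(arrivals[d], (tr[valid], tc[valid]), cnt[valid])
        lost = float(sent.sum() - arrivals.sum())
        diag.lost_at_sea += lost

        # -- long-distance dispersal --
        if ldd_active and ldd_counts.sum() > 0:
            occupancy = grown >= 1.0
            n_ldd = int(ldd_counts.sum())
            diag.ldd_sent += n_ldd
            src_flat = np.repeat(occ_idx, ldd_counts)
            x = _sample_ldd_distances(n_ldd, params.alpha, params.mu_bar, rng)
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n_ldd)
            tr = np.rint(src_flat // C + x * np.sin(theta)).astype(np.int64)
            tc = np.rint(src_flat % C + x * np.cos(theta)).astype(np.int64)
            ok = (tr >= 0) & (tr < R) & (tc >= 0) & (tc < C)
            ok[ok] &= habitable[tr[ok], tc[ok]]
            if scenario.ldd_regime == "empty_only":
                ok[ok] &= ~occupancy[tr[ok], tc[ok]]
            elif scenario.ldd_regime == "occupied_only":
                ok[ok] &= occupancy[tr[ok], tc[ok]]
            diag.ldd_discarded += float(n_ldd - ok.sum())
            if ok.any():
                tgt_flat = tr[ok] * C + tc[ok]
                key = tgt_flat * ncell + src_flat[ok]
                uniq, cnt = np.unique(key, return_counts=True)
                ldd_arrivals[tau] = np.column_stack(
                    [uniq // ncell, uniq % ncell, cnt]
                ).astype(np.int32)
                diag.ldd_arrived += float(cnt.sum())

        adj_arrivals[tau] = arrivals
        new = grown - emig.reshape(R, C)
        new += arrivals.sum(axis=0)
        if ldd_arrivals[tau] is not None:
            a = ldd_arrivals[tau]
            np.add.at(new.ravel(), a[:, 0], a[:, 2].astype(np.float64))
        new[~habitable] = 0.0
        diag.arrivals = diag.emigrants - diag.lost_at_sea - diag.ldd_discarded
        densities[tau + 1] = new

    return DemographyRecord(
        landscape, scenario, params, densities, adj_arrivals, ldd_arrivals, diag
    )
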