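"""Lattice world: masks, habitability through time, least-cost distances.

The world is a rectangular grid of square demes.  Each cell is sea, plain
land, barrier (land but never habitable, e.g. desert/high mountain bands),
corridor (land that opens only at the out-of-Africa time ``T_OOA``) or
refuge (land that stays habitable through the glacial contraction).  Time is
measured in generations before present (BP), 25 years per generation.

Configurations are plain-text YAML documents carrying an ASCII grid block::

    deme_side_km: 150
    origin: [10, 3]
    grid: |
      ....LLL...
      .LLLRRL...
    samples:
      - {label: Yoruba, row: 1, col: 2, n: 15, group: AFR}
    crossings:
      - [[4, 10], [4, 12]]   # optional short sea-crossing edges

Grid characters: ``.`` sea, ``L`` land, ``B`` barrier, ``C`` corridor,
``R`` refuge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

GRID_CHARS = {".": "sea", "L": "land", "B": "barrier", "C": "corridor", "R": "refuge"}
GROUPS = ("AFR", "ENA", "CAS", "EAS")

#: fixed epoch constants (generations BP)
T_SCONTR_DEFAULT = 1000
REFUGE_DURATION_DEFAULT = 160
CONTRACTION_DURATION = 120
T_NEOLITHIC = 320


class LandscapeConfigError(ValueError):
    """Raised when a landscape configuration violates its invariants."""


@dataclass(frozen=True)
class SampleSite:
    """One sampled population: deme coordinate, size and regional group."""

    label: str
    row: int
    col: int
    n_diploid: int
    group: str


@dataclass
class Landscape:
    """A validated lattice world.

    ``land_mask`` marks every land cell (including barriers, corridors and
    refugia); ``barrier_mask`` cells are land but never habitable;
    ``corridor_mask`` cells are habitable only from ``T_OOA`` onward
    (backward-in-time labelling: habitable for t <= T_OOA);
    ``refugia_mask`` cells remain habitable during the contraction refuge
    phase.
    """

    n_rows: int
    n_cols: int
    land_mask: np.ndarray
    barrier_mask: np.ndarray
    corridor_mask: np.ndarray
    refugia_mask: np.ndarray
    deme_side_km: float
    origin: tuple[int, int]
    samples: list[SampleSite]
    crossings: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)

    # -- derived helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def base_habitable(self) -> np.ndarray:
        """Cells habitable before the corridor opens: land minus barriers
        and corridors."""
        return self.land_mask & ~self.barrier_mask & ~self.corridor_mask

    @property
    def habitable_after_ooa(self) -> np.ndarray:
        return self.land_mask & ~self.barrier_mask

    @property
    def group_assignment(self) -> dict[str, str]:
        return {s.label: s.group for s in self.samples}

    @property
    def sample_coords(self) -> list[tuple[tuple[int, int], int]]:
        return [((s.row, s.col), s.n_diploid) for s in self.samples]

    def counts(self) -> dict[str, int]:
        """Cell counts by class, for reporting."""
        return {
            "land": int(self.land_mask.sum()),
            "barrier": int(self.barrier_mask.sum()),
            "corridor": int(self.corridor_mask.sum()),
            "refuge": int(self.refugia_mask.sum()),
        }

    def validate(self) -> None:
        r, c = self.origin
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise LandscapeConfigError(f"origin {self.origin} outside the grid")
        if not self.land_mask[r, c] or self.barrier_mask[r, c]:
            raise LandscapeConfigError(f"origin {self.origin} is not on habitable land")
        if (self.refugia_mask & ~self.land_mask).any():
            raise LandscapeConfigError("refugia_mask contains sea cells")
        if (self.corridor_mask & self.barrier_mask).any():
            raise LandscapeConfigError("corridor and barrier masks overlap")
        for s in self.samples:
            if not (0 <= s.row < self.n_rows and 0 <= s.col < self.n_cols):
                raise LandscapeConfigError(f"sample {s.label!r} at ({s.row},{s.col}) outside grid")
            if not self.land_mask[s.row, s.col] or self.barrier_mask[s.row, s.col]:
                raise LandscapeConfigError(
                    f"sample {s.label!r} at ({s.row},{s.col}) is on sea or barrier"
                )
            if s.group not in GROUPS:
                raise LandscapeConfigError(f"sample {s.label!r}: unknown group {s.group!r}")
            if s.n_diploid < 1:
                raise LandscapeConfigError(f"sample {s.label!r}: sample size must be >= 1")


def build_landscape(config: str | dict) -> Landscape:
    """Parse and validate a landscape configuration.

    ``config`` is YAML text (or an equivalent mapping) as documented in the
    module docstring.  Raises :class:`LandscapeConfigError` naming the
    offending deme on any invariant violation.
    """
    if isinstance(config, str):
        config = yaml.safe_load(config)
    grid_lines = [ln for ln in config["grid"].splitlines() if ln.strip()]
    n_rows = len(grid_lines)
    n_cols = len(grid_lines[0])
    if any(len(ln) != n_cols for ln in grid_lines):
        raise LandscapeConfigError("grid rows have unequal lengths")
    chars = np.array([list(ln) for ln in grid_lines])
    unknown = set(chars.ravel()) - set(GRID_CHARS)
    if unknown:
        raise LandscapeConfigError(f"unknown grid characters: {sorted(unknown)}")

    land = chars != "."
    barrier = chars == "B"
    corridor = chars == "C"
    refuge = chars == "R"

    samples = [
        SampleSite(s["label"], int(s["row"]), int(s["col"]), int(s["n"]), s["group"])
        for s in config.get("samples", [])
    ]
    crossings = [
        (tuple(a), tuple(b)) for a, b in config.get("crossings", [])
    ]
    lsc = Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        land_mask=land,
        barrier_mask=barrier,
        corridor_mask=corridor,
        refugia_mask=refuge,
        deme_side_km=float(config.get("deme_side_km", 150.0)),
        origin=tuple(config["origin"]),
        samples=samples,
        crossings=crossings,
    )
    lsc.validate()
    return lsc


# ---------------------------------------------------------------------------
# Glacial range contraction schedule
# ---------------------------------------------------------------------------


@dataclass
class ContractionSchedule:
    """Timing of the glacial range contraction.

    ``n_events`` contraction events, ``inter_event_gaps[i]`` generations
    apart, each removing ``layers_per_event[i]`` latitudinal rows of
    habitable demes (refuge cells are spared).  After the last event only
    the refugia remain habitable, for ``refuge_duration_gen`` generations,
    after which the full range reopens for recolonisation.
    """

    t_start_gen: int = T_SCONTR_DEFAULT
    n_events: int = 30
    inter_event_gaps: list[int] = field(default_factory=lambda: [4] * 30)
    layers_per_event: list[int] | None = None
    refuge_duration_gen: int = REFUGE_DURATION_DEFAULT

    def __post_init__(self):
        if len(self.inter_event_gaps) != self.n_events:
            raise ValueError("need one inter-event gap per event")
        if any(g not in (2, 4) for g in self.inter_event_gaps):
            raise ValueError("inter-event gaps must be 2 or 4 generations")

    @property
    def duration(self) -> int:
        return int(sum(self.inter_event_gaps))

    @property
    def t_end_gen(self) -> int:
        """Time BP at which the contraction is complete."""
        return self.t_start_gen - self.duration

    @property
    def t_release_gen(self) -> int:
        """Time BP at which refugial populations are released."""
        return self.t_end_gen - self.refuge_duration_gen

    def event_times(self) -> np.ndarray:
        """Times BP of the contraction events (first event at t_start)."""
        gaps = np.asarray(self.inter_event_gaps)
        return self.t_start_gen - (np.cumsum(gaps) - gaps[0])

    def layers_for(self, landscape: Landscape) -> list[list[int]]:
        """Rows removed at each event, north to south toward the refugia.

        If ``layers_per_event`` was not given, the rows holding non-refuge
        habitable demes are split into ``n_events`` nearly equal chunks so
        that after the final event exactly the refugia remain.
        """
        removable = landscape.habitable_after_ooa & ~landscape.refugia_mask
        rows = [r for r in range(landscape.n_rows) if removable[r].any()]
        if self.layers_per_event is not None:
            chunks, i = [], 0
            for w in self.layers_per_event:
                chunks.append(rows[i : i + w])
                i += w
            if i < len(rows):  # remainder collapses into the last event
                chunks[-1] = chunks[-1] + rows[i:]
            return chunks
        splits = np.array_split(np.array(rows, dtype=int), self.n_events)
        return [list(s) for s in splits]


# ---------------------------------------------------------------------------
# Carrying capacity through time
# ---------------------------------------------------------------------------


def capacity_at(landscape, schedule, scenario, params, t: int) -> np.ndarray:
    """Diploid carrying-capacity grid at time ``t`` generations BP.

    Piecewise constant in ``t`` with breakpoints at the corridor opening
    (``T_OOA``), the contraction event times, the refuge release, and the
    Neolithic size increase (320 generations BP).  Returns 0 on sea,
    barriers and currently uninhabitable demes.

    ``schedule`` may be None (no range contraction); ``scenario`` supplies
    the range-contraction and Neolithic flags; ``params`` supplies K, T_OOA
    and (for Neolithic scenarios) KNeo.
    """
    K = np.zeros(landscape.shape, dtype=float)
    habitable = (
        landscape.habitable_after_ooa if t <= params.T_OOA else landscape.base_habitable
    )
    habitable = habitable.copy()

    if scenario.range_contraction and schedule is not None:
        if schedule.t_end_gen >= t > schedule.t_release_gen:
            # refuge phase (contraction finished, release not yet reached)
            habitable &= landscape.refugia_mask
        elif schedule.t_start_gen >= t > schedule.t_end_gen:
            removed = np.zeros(landscape.n_rows, dtype=bool)
            layers = schedule.layers_for(landscape)
            for t_ev, rows in zip(schedule.event_times(), layers):
                if t <= t_ev:
                    removed[rows] = True
            keep = ~removed[:, None] | landscape.refugia_mask
            habitable &= keep

    k_value = params.K
    if scenario.neolithic and t < getattr(scenario, "t_neolithic", T_NEOLITHIC):
        k_value = params.KNeo
    K[habitable] = k_value
    return K


# ---------------------------------------------------------------------------
# Least-cost distances
# ---------------------------------------------------------------------------


def _passable(landscape: Landscape) -> np.ndarray:
    # corridors count as land for routing: distances describe the post-OOA world
    return landscape.land_mask & ~landscape.barrier_mask


def _graph(landscape: Landscape, routing: str) -> csr_matrix:
    if routing not in ("levant_only", "levant_horn_gibraltar"):
        raise ValueError(f"unknown routing {routing!r}")
    ok = _passable(landscape)
    n = landscape.n_rows * landscape.n_cols
    idx = np.arange(n).reshape(landscape.shape)
    rows, cols, w = [], [], []
    side = landscape.deme_side_km
    # 4-neighbour lattice edges (von Neumann)
    for dr, dc in ((0, 1), (1, 0)):
        a = ok[: landscape.n_rows - dr, : landscape.n_cols - dc]
        b = ok[dr:, dc:]
        both = a & b
        src = idx[: landscape.n_rows - dr, : landscape.n_cols - dc][both]
        dst = idx[dr:, dc:][both]
        rows.extend(src)
        cols.extend(dst)
        w.extend([side] * len(src))
    if routing == "levant_horn_gibraltar":
        for (r1, c1), (r2, c2) in landscape.crossings:
            if not (ok[r1, c1] and ok[r2, c2]):
                raise LandscapeConfigError(
                    f"crossing endpoint ({r1},{c1})-({r2},{c2}) not on passable land"
                )
            rows.append(idx[r1, c1])
            cols.append(idx[r2, c2])
            w.append(side * float(np.hypot(r2 - r1, c2 - c1)))
    m = csr_matrix((np.array(w), (np.array(rows), np.array(cols))), shape=(n, n))
    return m + m.T


def least_cost_distance(
    landscape: Landscape,
    origin: tuple[int, int] | None = None,
    routing: str = "levant_only",
) -> dict[str, float]:
    """Shortest over-land distance (km) from the origin to every sample.

    Sea and barrier demes are impassable; lattice steps cost one deme side.
    Under ``levant_horn_gibraltar`` routing the configured short
    sea-crossing edges are additionally traversable.  Raises
    :class:`LandscapeConfigError` naming any unreachable sampled deme.
    """
    if origin is None:
        origin = landscape.origin
    g = _graph(landscape, routing)
    src = origin[0] * landscape.n_cols + origin[1]
    dist = dijkstra(g, directed=False, indices=src)
    out = {}
    for s in landscape.samples:
        d = dist[s.row * landscape.n_cols + s.col]
        if not np.isfinite(d):
            raise LandscapeConfigError(
                f"sampled deme {s.label!r} at ({s.row},{s.col}) unreachable "
                f"from origin under {routing} routing"
            )
        out[s.label] = float(d)
    return out


def distance_table(landscape: Landscape, routing: str = "levant_only"):
    """Distances as a pandas DataFrame (TSV-ready: deme_row, deme_col,
    population_label, distance_km, routing)."""
    import pandas as pd

    d = least_cost_distance(landscape, routing=routing)
    return pd.DataFrame(
        {
            "deme_row": [s.row for s in landscape.samples],
            "deme_col": [s.col for s in landscape.samples],
            "population_label": [s.label for s in landscape.samples],
            "distance_km": [d[s.label] for s in landscape.samples],
            "routing": routing,
        }
    )
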