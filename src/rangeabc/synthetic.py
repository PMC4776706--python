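"""Everything the pipeline needs without downloads: priors, fixture
landscapes, and pseudo-observed genotype panels.

Two prior files ship with the package:

``priors.yaml``
    The study-scale conditions: printed priors (STR_MUTRATE ~ U[5e-5,
    3e-4], KNeo ~ U[2500, 7500], T_STARTEXP ~ U[3200, 6000] generations,
    T_OOA ~ U[1200, 3000]) plus reconstructed supports for the remaining
    parameters (smallest round intervals containing the reported 95%
    HPDIs), and the fixed epoch constants (contraction onset 1000
    generations BP, 30 events 4 generations apart, 160-generation refuge
    phase, Neolithic increase 320 generations BP, 6-deme LDD cap).

``priors_mini.yaml``
    Desk-scale conditions for the mini fixture: rate-like parameters keep
    their study supports, the time axis is compressed (shorter expansion,
    earlier and briefer contraction) and per-step drift is strengthened
    (smaller K, lower m) so the serial-founder diversity gradient forms
    on the smaller map and a full simulation takes a fraction of a
    second.  Used by the scaled-down power and recovery studies.

Fixture landscapes (ASCII grids, generated once and packaged as plain
text with a manifest): ``strip-16`` (1x16 demes, analytic checks),
``island-pair`` (two demes, coalescent/R_ST oracles),
``schematic-old-world-small`` (30x60 Africa-Eurasia topology with Levant
corridor, Sahara and Himalaya barriers, four refuge blocks, Gibraltar and
Horn-of-Africa sea crossings, 22 sampled populations in 4 groups) and
``schematic-old-world-mini`` (12x24, 8 populations — the power-study
workhorse).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import yaml

from .coalescent import SamplingDesign, simulate_dataset
from .forward import SCENARIOS, ParamVector, ScenarioSpec, run_forward
from .landscape import ContractionSchedule, Landscape, build_landscape

PARAM_ORDER = (
    "T_STARTEXP",
    "T_OOA",
    "Ne_ANC",
    "K",
    "r",
    "m",
    "LDD_PROP",
    "mu_bar",
    "alpha",
    "STR_MUTRATE",
    "KNeo",
)

_INT_PARAMS = {"T_STARTEXP", "T_OOA"}


class ExtinctionError(RuntimeError):
    """A forward replicate went extinct or cannot supply the samples; the
    caller should redraw (failed replicates are rejected, not fatal)."""


@dataclass
class PriorSpec:
    """Uniform prior supports plus the scenario's fixed constants."""

    bounds: dict[str, tuple[float, float]]
    constants: dict

    @classmethod
    def from_yaml(cls, text: str) -> "PriorSpec":
        doc = yaml.safe_load(text)
        bounds = {}
        for name, spec in doc["parameters"].items():
            if spec.get("dist", "uniform") != "uniform":
                raise ValueError(f"parameter {name}: only uniform priors are supported")
            lo, hi = float(spec["lower"]), float(spec["upper"])
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"parameter {name}: invalid bounds [{lo}, {hi}]")
            bounds[name] = (lo, hi)
        return cls(bounds, doc.get("constants", {}))

    @classmethod
    def load(cls, name: str = "priors") -> "PriorSpec":
        text = resources.files("rangeabc").joinpath("data", f"{name}.yaml").read_text()
        return cls.from_yaml(text)

    def schedule(self) -> ContractionSchedule:
        c = self.constants
        return ContractionSchedule(
            t_start_gen=int(c.get("T_SCONTR", 1000)),
            n_events=int(c.get("n_contraction_events", 30)),
            inter_event_gaps=[int(c.get("contraction_gap", 4))] * int(c.get("n_contraction_events", 30)),
            refuge_duration_gen=int(c.get("refuge_duration", 160)),
        )

    def scenario(self, name: str) -> ScenarioSpec:
        base = SCENARIOS[name]
        return ScenarioSpec(
            ldd_regime=base.ldd_regime,
            range_contraction=base.range_contraction,
            neolithic=base.neolithic,
            deme_side_km=float(self.constants.get("deme_side_km", 150.0)),
            t_neolithic=int(self.constants.get("t_neolithic", 320)),
        )


def sample_prior(priors: PriorSpec, scenario, seed) -> ParamVector:
    """Independent uniform draws; parameters irrelevant to the scenario
    (LDD kernel under noLDD, KNeo outside Neolithic models) are set to 0."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    vals = {}
    for name in PARAM_ORDER:
        lo, hi = priors.bounds[name]
        x = rng.uniform(lo, hi)
        vals[name] = int(round(x)) if name in _INT_PARAMS else float(x)
    if not scenario.has_ldd:
        vals["LDD_PROP"] = 0.0
        vals["mu_bar"] = 0.0
        vals["alpha"] = 0.0
    if not scenario.neolithic:
        vals["KNeo"] = 0.0
    return ParamVector(**vals)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "strip-16": "strip16.yaml",
    "island-pair": "island_pair.yaml",
    "schematic-old-world-small": "schematic_old_world_small.yaml",
    "schematic-old-world-mini": "schematic_old_world_mini.yaml",
}


def load_fixture(name: str) -> Landscape:
    """Load one packaged fixture landscape by name."""
    try:
        fname = FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(FIXTURE_FILES)}") from None
    text = resources.files("rangeabc").joinpath("data", fname).read_text()
    return build_landscape(text)


def fixture_manifest() -> dict:
    """The documented manifest of the packaged fixtures (cell counts,
    sample composition)."""
    text = resources.files("rangeabc").joinpath("data", "fixtures_manifest.yaml").read_text()
    return yaml.safe_load(text)


def fixture_suite() -> dict[str, Landscape]:
    """All packaged fixture landscapes, loaded and validated."""
    return {name: load_fixture(name) for name in FIXTURE_FILES}


def constant_deme_record(n_genes: float, n_steps: int, ne_anc: float):
    """A hand-built demography: one deme at constant density, no migration.

    With ``ne_anc == n_genes/2`` the whole history (recorded span plus
    ancestral phase) is a constant population of ``n_genes`` gene copies —
    the reference case for closed-form coalescent and mutation checks
    (mean pairwise TMRCA, SMM equilibrium heterozygosity).
    """
    import numpy as np

    from .forward import DemographyRecord, Diagnostics

    lsc = build_landscape(
        {
            "deme_side_km": 150,
            "origin": [0, 0],
            "grid": "L\n",
            "samples": [{"label": "P0", "row": 0, "col": 0, "n": 5, "group": "AFR"}],
        }
    )
    dens = np.full((n_steps + 1, 1, 1), n_genes, dtype=np.float32)
    adj = np.zeros((n_steps, 4, 1, 1), dtype=np.int32)
    params = ParamVector(
        T_STARTEXP=max(n_steps, 2), T_OOA=1, Ne_ANC=ne_anc, K=n_genes / 2, r=0.5, m=0.0
    )
    return DemographyRecord(
        lsc, ScenarioSpec(), params, dens, adj, [None] * n_steps, Diagnostics()
    )


# ---------------------------------------------------------------------------
# pseudo-observed panels
# ---------------------------------------------------------------------------


def make_pseudo_observed(
    scenario,
    params: ParamVector,
    landscape: Landscape,
    n_loci: int = 87,
    missing_rate: float = 0.0,
    seed=0,
    schedule: ContractionSchedule | None = None,
):
    """One pseudo-observed genotype panel: forward demography plus backward
    coalescent at the landscape's sampling design.

    Raises :class:`ExtinctionError` when the replicate dies out or cannot
    cover the samples (callers redraw).  Deterministic given the seed.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if missing_rate > 0.05:
        raise ValueError("missing rate above the 5% panel filter")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    record = run_forward(landscape, scenario, params, rng, schedule=schedule)
    if record.extinct:
        raise ExtinctionError("metapopulation extinct before present")
    design = SamplingDesign.from_landscape(landscape, n_loci=n_loci)
    from .coalescent import RecordConsistencyError

    try:
        design.validate_against(record)
    except RecordConsistencyError as e:
        raise ExtinctionError(str(e)) from e
    ds = simulate_dataset(record, design, params.STR_MUTRATE, rng)
    if missing_rate > 0:
        ds = ds.inject_missing(missing_rate, rng)
    return ds
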