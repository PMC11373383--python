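"""Coalescent training-data generator for sweep classification.

Six evaluation scenarios pair a hard, complete selective sweep
(selection coefficient 0.02, beneficial site at the region centre)
with a confounding demography: mild/severe population bottleneck
(D1/D2), recent/old divergence of two sampled demes ("migration",
D3/D4), and a central recombination hotspot of low/high intensity
(D5/D6).  Times in the scenario files are in coalescent units of
4*N0 generations with a present-day population of N0 = 50 000
diploids; the module converts them to generations for the msprime
engine.

Sweeps are simulated with msprime's structured-coalescent sweep model:
a standard coalescent phase covering the time since fixation, the
sweep phase, then the standard coalescent again.  Because that model
supports a single population, the two-deme scenarios are composed:
each deme is simulated independently back to the join time (with the
sweep inside the sampled deme when it predates the join), the lineages
are merged with ``tskit.union``, and the ancestral population is
continued (with the sweep there when it postdates the join).  Mutations
are laid down under the infinite-sites binary model, so every site is
biallelic with a known ancestral state.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import msprime
import numpy as np
import tskit
import yaml

from .representation import SNPMatrix, extract_center_window

SCENARIO_IDS = ("D1", "D2", "D3", "D4", "D5", "D6")
CLASSES = ("neutral", "sweep")

#: bounded resimulation when a replicate has fewer SNPs than the window
RETRY_CAP = 10


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    """One evaluation scenario (confounder + sweep parameters).

    Times (``onset``, ``duration``, ``join_time``, ``sweep_start``) are
    in units of 4*N0 generations; ``severity`` is a population size
    relative to N0; ``theta``/``rho`` are 4*N0*mu*L and 4*N0*r*L over
    the simulated region.
    """

    id: str
    confounder: str  # bottleneck | migration | hotspot | none
    present_size: int = 50_000
    selection_coefficient: float = 0.02
    sweep_start: float = 0.016
    # bottleneck
    severity: Optional[float] = None
    duration: Optional[float] = None
    onset: Optional[float] = None
    # migration
    join_time: Optional[float] = None
    sample_split: float = 0.5
    # hotspot
    hotspot_intensity: Optional[float] = None
    hotspot_span: float = 5000.0
    # region
    theta: float = 200.0
    rho: float = 200.0
    sequence_length: float = 100_000.0

    def __post_init__(self):
        if self.confounder not in ("bottleneck", "migration", "hotspot", "none"):
            raise ValueError(f"unknown confounder {self.confounder!r}")
        if self.theta <= 0 or self.rho < 0 or self.sequence_length <= 0:
            raise ValueError("theta, rho, sequence_length must be positive")
        if self.selection_coefficient <= 0:
            raise ValueError("selection coefficient must be positive")
        needed = {
            "bottleneck": ("severity", "duration", "onset"),
            "migration": ("join_time",),
            "hotspot": ("hotspot_intensity",),
            "none": (),
        }[self.confounder]
        for f in needed:
            if getattr(self, f) is None:
                raise ValueError(f"{self.confounder} scenario requires {f}")

    # unit conversions -------------------------------------------------------
    @property
    def time_unit(self) -> float:
        """Generations per coalescent time unit (4 * N0)."""
        return 4.0 * self.present_size

    @property
    def mutation_rate(self) -> float:
        return self.theta / (self.time_unit * self.sequence_length)

    @property
    def recombination_rate(self) -> float:
        return self.rho / (self.time_unit * self.sequence_length)

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


def load_scenario(scenario_id: str) -> ScenarioConfig:
    """Load a committed scenario config (D1..D6 or CONST) by id."""
    name = scenario_id.lower() if scenario_id != "CONST" else "const"
    ref = importlib.resources.files("dafnet.configs") / f"{name}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError as e:
        raise ValueError(f"unknown scenario {scenario_id!r}") from e
    return ScenarioConfig(**yaml.safe_load(text))


@dataclass(frozen=True)
class DatasetSpec:
    """Dataset sizes and seeding for one scenario.

    Defaults match the evaluation protocol: 1700/300/2000 windows per
    split, each evenly divided between the neutral and sweep classes,
    128 haplotypes, 128-SNP centre windows.
    """

    n_train: int = 1700
    n_val: int = 300
    n_test: int = 2000
    sample_size: int = 128
    window_width: int = 128
    seed: int = 0

    def __post_init__(self):
        for name in ("n_train", "n_val", "n_test"):
            n = getattr(self, name)
            if n <= 0 or n % 2:
                raise ValueError(f"{name} must be positive and even (got {n})")
        if self.sample_size < 1 or self.window_width < 1:
            raise ValueError("sample_size and window_width must be >= 1")


# ---------------------------------------------------------------------------
# engine plumbing
# ---------------------------------------------------------------------------

def _engine_seeds(seed: int, attempt: int, n: int) -> List[int]:
    """Derive n independent engine seeds in [1, 2^31-2] deterministically."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(attempt),))
    state = ss.generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 2)) + 1 for s in state]


def _sweep_model_sequence(scenario: ScenarioConfig, offset_gens: float = 0.0):
    """Standard coalescent up to fixation, sweep phase, standard again.

    ``offset_gens`` shifts the pre-sweep phase when the simulation
    starts in the past (deme continuation after a join).
    """
    n0 = scenario.present_size
    fixation_gens = scenario.sweep_start * scenario.time_unit - offset_gens
    if fixation_gens < 0:
        raise SimulationError("sweep predates the start of this simulation phase")
    sweep = msprime.SweepGenicSelection(
        position=scenario.sequence_length / 2,
        start_frequency=1.0 / (2 * n0),
        end_frequency=1.0 - 1.0 / (2 * n0),
        s=scenario.selection_coefficient,
        dt=1e-6,
    )
    return [
        msprime.StandardCoalescent(duration=fixation_gens),
        sweep,
        msprime.StandardCoalescent(),
    ]


def _bottleneck_demography(scenario: ScenarioConfig) -> msprime.Demography:
    n0 = scenario.present_size
    dem = msprime.Demography()
    dem.add_population(initial_size=n0)
    if scenario.confounder == "bottleneck":
        t0 = scenario.onset * scenario.time_unit
        t1 = (scenario.onset + scenario.duration) * scenario.time_unit
        dem.add_population_parameters_change(
            time=t0, initial_size=scenario.severity * n0
        )
        dem.add_population_parameters_change(time=t1, initial_size=n0)
    return dem


def _recombination(scenario: ScenarioConfig):
    if scenario.confounder != "hotspot":
        return scenario.recombination_rate
    L = scenario.sequence_length
    half = scenario.hotspot_span / 2
    base = scenario.recombination_rate
    return msprime.RateMap(
        position=[0.0, L / 2 - half, L / 2 + half, L],
        rate=[base, scenario.hotspot_intensity * base, base],
    )


def _collapse_populations(ts: tskit.TreeSequence) -> tskit.TreeSequence:
    """Rewrite all nodes into a single population 0."""
    tables = ts.dump_tables()
    tables.populations.clear()
    tables.populations.metadata_schema = tskit.MetadataSchema.null()
    tables.populations.add_row()
    tables.nodes.population = np.zeros(len(tables.nodes), dtype=np.int32)
    return tables.tree_sequence()


def _simulate_single_pop(
    scenario: ScenarioConfig, cls: str, n_hap: int, seeds: List[int]
) -> tskit.TreeSequence:
    model = (
        _sweep_model_sequence(scenario)
        if cls == "sweep"
        else msprime.StandardCoalescent()
    )
    return msprime.sim_ancestry(
        samples=n_hap,
        ploidy=1,
        demography=_bottleneck_demography(scenario),
        sequence_length=scenario.sequence_length,
        recombination_rate=_recombination(scenario),
        discrete_genome=False,
        model=model,
        random_seed=seeds[0],
    )


def _simulate_two_demes(
    scenario: ScenarioConfig, cls: str, n_hap: int, seeds: List[int]
) -> tskit.TreeSequence:
    """Two demes of size N0 joining ``join_time`` ago, sampled jointly.

    The sweep (when present) runs inside deme A if it completes before
    the join looking backwards, otherwise in the merged ancestral
    population.
    """
    n0 = scenario.present_size
    join_gens = scenario.join_time * scenario.time_unit
    sweep_gens = scenario.sweep_start * scenario.time_unit
    n_a = round(scenario.sample_split * n_hap)
    n_b = n_hap - n_a
    sweep_in_deme = cls == "sweep" and sweep_gens < join_gens
    sweep_in_merged = cls == "sweep" and not sweep_in_deme
    rec = _recombination(scenario)

    def deme(n, seed, with_sweep):
        model = (
            _sweep_model_sequence(scenario)
            if with_sweep
            else msprime.StandardCoalescent()
        )
        return msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=n0,
            sequence_length=scenario.sequence_length,
            recombination_rate=rec,
            discrete_genome=False,
            model=model,
            end_time=join_gens,
            random_seed=seed,
        )

    ts_a = deme(n_a, seeds[0], sweep_in_deme)
    ts_b = deme(n_b, seeds[1], False)
    merged = ts_a.union(
        ts_b,
        node_mapping=np.full(ts_b.num_nodes, tskit.NULL),
        add_populations=False,
    )
    merged = _collapse_populations(merged)
    model = (
        _sweep_model_sequence(scenario, offset_gens=join_gens)
        if sweep_in_merged
        else msprime.StandardCoalescent()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # null population-metadata schema
        return msprime.sim_ancestry(
            initial_state=merged,
            population_size=n0,
            recombination_rate=rec,
            discrete_genome=False,
            model=model,
            random_seed=seeds[2],
        )


def _ts_to_matrix(
    mts: tskit.TreeSequence, scenario: ScenarioConfig, cls: str
) -> SNPMatrix:
    geno = mts.genotype_matrix()  # (sites, haplotypes), 0 ancestral / 1 derived
    pos = mts.tables.sites.position
    seg = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < geno.shape[1])
    geno, pos = geno[seg], pos[seg]
    return SNPMatrix(
        alleles=geno.T.astype(np.int8),
        positions=pos / scenario.sequence_length,
        label=cls,
        scenario_id=scenario.id,
    )


def simulate_replicate(
    scenario: ScenarioConfig,
    cls: str,
    rng_seed: int,
    sample_size: int = 128,
    min_snps: int = 128,
) -> SNPMatrix:
    """Simulate one polarized replicate with at least ``min_snps`` SNPs.

    Deterministic in ``rng_seed``.  Replicates that come out shorter
    than ``min_snps`` are resimulated with a fresh derived seed up to
    a bounded retry cap.
    """
    if cls not in CLASSES:
        raise ValueError(f"class must be one of {CLASSES}")
    for attempt in range(RETRY_CAP):
        seeds = _engine_seeds(rng_seed, attempt, 4)
        if scenario.confounder == "migration":
            ts = _simulate_two_demes(scenario, cls, sample_size, seeds)
        else:
            ts = _simulate_single_pop(scenario, cls, sample_size, seeds)
        mts = msprime.sim_mutations(
            ts,
            rate=scenario.mutation_rate,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=seeds[3],
        )
        matrix = _ts_to_matrix(mts, scenario, cls)
        if matrix.n_snps >= min_snps:
            return matrix
    raise SimulationError(
        f"{scenario.id}/{cls}: fewer than {min_snps} SNPs after "
        f"{RETRY_CAP} attempts (seed {rng_seed})"
    )


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class LabeledWindows:
    """One dataset split: centre windows plus integer labels (0=neutral, 1=sweep)."""

    matrices: List[SNPMatrix]
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.matrices)

    def features(self, scale: Optional[float] = None) -> Tuple[np.ndarray, np.ndarray]:
        """Stack the 2 x W feature matrices into an (n, 2, W) array."""
        from .representation import featurize

        x = np.stack([featurize(m, scale=scale).as_array() for m in self.matrices])
        return x, self.labels.copy()


@dataclass
class Dataset:
    scenario_id: str
    spec: DatasetSpec
    train: LabeledWindows
    val: LabeledWindows
    test: LabeledWindows

    @property
    def splits(self) -> Dict[str, LabeledWindows]:
        return {"train": self.train, "val": self.val, "test": self.test}


def replicate_seed(master_seed: int, split: str, index: int) -> int:
    """Deterministic per-replicate seed, reproducible in isolation."""
    split_idx = ("train", "val", "test").index(split)
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(1000 + split_idx, int(index))
    )
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31 - 2)) + 1


def make_dataset(scenario: ScenarioConfig, spec: DatasetSpec) -> Dataset:
    """Simulate the train/val/test splits for a scenario.

    Each split is exactly class balanced; every replicate is cut to its
    central ``window_width`` SNPs; per-replicate seeds derive from
    ``spec.seed`` so any single window can be regenerated alone.
    """
    out = {}
    for split, total in (
        ("train", spec.n_train),
        ("val", spec.n_val),
        ("test", spec.n_test),
    ):
        mats: List[SNPMatrix] = []
        labels = np.zeros(total, dtype=np.int64)
        for k in range(total):
            cls = "neutral" if k < total // 2 else "sweep"
            labels[k] = CLASSES.index(cls)
            m = simulate_replicate(
                scenario,
                cls,
                replicate_seed(spec.seed, split, k),
                sample_size=spec.sample_size,
                min_snps=spec.window_width,
            )
            mats.append(extract_center_window(m, spec.window_width))
        out[split] = LabeledWindows(mats, labels)
    return Dataset(scenario.id, spec, out["train"], out["val"], out["test"])


# ---------------------------------------------------------------------------
# deterministic toy fixtures
# ---------------------------------------------------------------------------

def make_toy_fixture(kind: str) -> SNPMatrix:
    """Tiny hand-written matrices with known DAF/distance outputs."""
    if kind == "all_derived":
        return SNPMatrix(
            alleles=np.ones((4, 4), dtype=np.int8),
            positions=np.array([0.1, 0.2, 0.3, 0.4]),
        )
    if kind == "checkerboard":
        a = np.indices((4, 4)).sum(axis=0) % 2
        return SNPMatrix(
            alleles=a.astype(np.int8), positions=np.array([0.1, 0.2, 0.3, 0.4])
        )
    if kind == "with_missing":
        a = np.array(
            [[1, 0, 1], [1, -1, 0], [-1, 1, 0], [0, 1, 1]], dtype=np.int8
        )
        return SNPMatrix(alleles=a, positions=np.array([0.25, 0.5, 0.75]))
    if kind == "sweep_like":
        # low diversity, DAFs at the extremes, SNPs crowded to the edges
        a = np.zeros((8, 8), dtype=np.int8)
        a[:, :4] = 1
        a[0, 4] = 1
        a[:7, 5] = 1
        a[0, 6] = 1
        a[:7, 7] = 1
        pos = np.array([0.01, 0.02, 0.03, 0.04, 0.96, 0.97, 0.98, 0.99])
        return SNPMatrix(alleles=a, positions=pos, label="sweep")
    if kind == "neutral_like":
        # intermediate frequencies, evenly spread positions
        rows = np.arange(8)
        a = (rows[:, None] < np.array([4, 3, 5, 4, 3, 5, 4, 4])[None, :]).astype(
            np.int8
        )
        pos = np.linspace(0.06, 0.94, 8)
        return SNPMatrix(alleles=a, positions=pos, label="neutral")
    raise ValueError(f"unknown toy fixture kind {kind!r}")


def make_toy_dataset(
    n_per_class: int, width: int = 16, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """A linearly separable DAF-style toy problem for training sanity.

    Sweep-like windows draw DAFs from the frequency extremes with
    crowded-then-sparse spacing; neutral-like windows draw intermediate
    DAFs with even spacing.  Returns ``(x, y)`` with x of shape
    ``(2 * n_per_class, 2, width)``.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            if cls == 1:
                daf = rng.beta(0.08, 0.08, size=width)
                gaps = rng.exponential(0.2, size=width - 1) + 1.2
            else:
                daf = rng.beta(8.0, 8.0, size=width)
                gaps = rng.exponential(1.0, size=width - 1) + 0.2
            dist = np.concatenate([gaps, [0.0]]) / (width * 2)
            xs.append(np.stack([daf, dist]).astype(np.float32))
            ys.append(cls)
    return np.asarray(xs), np.asarray(ys, dtype=np.int64)
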