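"""Labeled training data from coalescent simulation.

Scenario parameter draws, a pluggable coalescent engine (the reference
engine delegates to msprime), the autotetraploid read-count simulator, and
builders that assemble class-rebalanced train/validation/test splits of
network-ready images for each inference task.

Model parameters that originate in prior work (the two-species
isolation-with-migration model, the bottleneck-plus-sweep scenario, the
three-epoch demographic ranges) are shipped here as clearly labeled,
user-replaceable artifact defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from .imageprep import (
    Encoding,
    PositionFeature,
    encode_alleles,
    pad_and_shape,
    positions_to_distances,
)
from .msio import HaplotypeAlignment

__all__ = [
    "RecombScenario", "ConstantThetaScenario", "DemographicModel3Epoch",
    "IntrogressionModel", "SweepScenario", "ReadFractionMatrix", "LabeledDataset",
    "MsprimeEngine", "DEFAULT_ENGINE",
    "draw_recomb_scenario", "draw_interpolation_scenario", "draw_demographic_model",
    "simulate_alignment", "make_tetraploid_reads",
    "build_theta_toy_dataset", "build_rho_dataset", "build_introgression_dataset",
    "build_sweep_dataset", "build_demography_dataset",
    "simulate_theta_toy", "simulate_demography",
    "DEMOGRAPHY_RANGES_DEFAULT", "INTROGRESSION_DEFAULTS", "SWEEP_DEFAULTS",
]

MU_DEFAULT = 1.5e-8  # per-bp per-generation mutation rate for the rho tasks
L_DEFAULT = 20_000  # locus length (bp) for the rho tasks
N_CHOICES_TRAIN = (5_000, 10_000, 15_000, 20_000, 50_000)
N_CHOICES_INTERPOLATION = (30_000, 35_000, 40_000, 45_000)
R_BOUNDS = (1e-8, 1e-6)  # truncation bounds for the crossover rate draw
R_EXP_MEAN = 1e-7  # mean of the (untruncated) exponential for r


# ---------------------------------------------------------------------------
# scenario types and draws


@dataclass
class RecombScenario:
    """Constant-size locus with free recombination rate.

    theta = 4*N*mu*L and rho_per_bp = 4*N*r follow from the fields.
    """

    N: float
    r: float
    mu: float = MU_DEFAULT
    L_bp: int = L_DEFAULT

    @property
    def theta(self) -> float:
        return 4.0 * self.N * self.mu * self.L_bp

    @property
    def rho_per_bp(self) -> float:
        return 4.0 * self.N * self.r


@dataclass
class ConstantThetaScenario:
    """Panmictic constant-size locus parameterized directly by theta."""

    theta: float
    L_bp: int = 10_000
    rho_per_bp: float = 0.0


@dataclass
class DemographicModel3Epoch:
    """Instantaneous size changes: N0 now, N1 after T1, N2 beyond T2 (T1 < T2).

    Sizes are diploid effective sizes; times are generations before present.
    """

    N0: float
    N1: float
    N2: float
    T1: float
    T2: float
    mu: float = 1.2e-9  # 1.2e-8 downsampled 10x to keep images tractable
    r: float = 1e-8
    L_bp: int = 1_500_000

    def __post_init__(self):
        if min(self.N0, self.N1, self.N2) <= 0:
            raise ValueError("population sizes must be positive")
        if not 0 < self.T1 < self.T2:
            raise ValueError("times must satisfy 0 < T1 < T2")

    def label(self) -> np.ndarray:
        return np.array([self.N0, self.N1, self.N2, self.T1, self.T2])


@dataclass
class IntrogressionModel:
    """Two-species isolation-with-migration model with a single pulse.

    ``direction`` 0 = no introgression, 1 = gene flow species1 -> species2,
    2 = species2 -> species1 (forward in time). Default parameter values
    are artifact defaults loosely shaped on a Drosophila-like species pair;
    replace them with an inferred joint history for real applications.
    """

    N1: float = 100_000
    N2: float = 50_000
    N_anc: float = 100_000
    T_split: float = 500_000
    T_mig: float = 25_000
    mig_prob: float = 0.25
    n1: int = 20
    n2: int = 14
    mu: float = 2.5e-9
    r: float = 1e-8
    L_bp: int = 10_000
    direction: int = 0


@dataclass
class SweepScenario:
    """A focal window that is swept, linked to a sweep, or neutral.

    A region of ``3 * window_bp`` is simulated under a stepwise size
    history; the selected site sits at the centre of the middle window for
    the ``hard``/``soft`` classes, at the centre of a random flanking
    window for the ``linked_*`` classes, and is absent for ``neutral``.
    The middle window is then cropped out and its positions rescaled to
    [0, 1]. Defaults are artifact defaults sketching a bottlenecked
    human-like population.
    """

    sweep_class: str = "neutral"  # hard | soft | linked_hard | linked_soft | neutral
    # stepwise sizes (time, diploid size); the first change is placed late
    # enough that a completing sweep's selected phase ends before it, which
    # the structured-coalescent sweep machinery requires
    size_history: tuple = ((0, 10_000), (2_000, 2_000), (5_000, 14_000))
    s: float = 0.05
    soft_freq_range: tuple[float, float] = (0.05, 0.20)
    soft_start_freq: float | None = None  # drawn from soft_freq_range if None
    mu: float = 1.2e-8
    r: float = 1e-8
    window_bp: int = 100_000
    linked_side: int = 0  # 0 = left flank, 1 = right flank

    CLASSES = ("hard", "soft", "linked_hard", "linked_soft", "neutral")


def _truncated_exponential(rng: np.random.Generator, mean: float,
                           bounds: tuple[float, float]) -> float:
    # rejection sampling; acceptance ~ 9% at the defaults, still instant
    while True:
        x = rng.exponential(mean)
        if bounds[0] <= x <= bounds[1]:
            return float(x)


def draw_recomb_scenario(rng: np.random.Generator,
                         n_choices=N_CHOICES_TRAIN) -> RecombScenario:
    """N uniform over the training set sizes; r from an exponential
    (mean 1e-7) truncated to [1e-8, 1e-6], giving rho/bp in [2e-4, 2e-1]."""
    N = float(rng.choice(n_choices))
    r = _truncated_exponential(rng, R_EXP_MEAN, R_BOUNDS)
    return RecombScenario(N=N, r=r)


def draw_interpolation_scenario(rng: np.random.Generator) -> RecombScenario:
    """As :func:`draw_recomb_scenario` with N in {30,35,40,45} thousand —
    population sizes never seen in training, used to probe interpolation."""
    return draw_recomb_scenario(rng, n_choices=N_CHOICES_INTERPOLATION)


DEMOGRAPHY_RANGES_DEFAULT = {
    # artifact defaults (the original ranges live in supplementary material):
    # sizes span 100-100,000 diploids; change times up to 4 x 10,000 generations
    "N0": (100.0, 100_000.0),
    "N1": (100.0, 100_000.0),
    "N2": (100.0, 100_000.0),
    "T1": (100.0, 20_000.0),
    "T2": (100.0, 40_000.0),
}


def draw_demographic_model(rng: np.random.Generator, ranges=None,
                           **model_kwargs) -> DemographicModel3Epoch:
    """Each parameter uniform in its range; (T1, T2) re-ordered so T1 < T2."""
    ranges = dict(DEMOGRAPHY_RANGES_DEFAULT if ranges is None else ranges)
    draws = {}
    for name, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi or lo < 0:
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        draws[name] = float(rng.uniform(lo, hi))
    t1, t2 = sorted((draws["T1"], draws["T2"]))
    if t1 == t2:  # measure-zero tie; nudge apart
        t2 = t1 * (1 + 1e-9) + 1e-9
    return DemographicModel3Epoch(N0=draws["N0"], N1=draws["N1"], N2=draws["N2"],
                                  T1=t1, T2=t2, **model_kwargs)


# ---------------------------------------------------------------------------
# the coalescent engine


def _alignment_from_ts(ts, L_bp: int, scenario_id: str = "") -> HaplotypeAlignment:
    if ts.num_sites == 0:
        return HaplotypeAlignment(
            np.zeros((ts.num_samples, 0), dtype=np.int8), np.zeros(0),
            locus_length_bp=L_bp, scenario_id=scenario_id)
    geno = ts.genotype_matrix().T.astype(np.int8)  # chroms x sites
    positions = np.array([s.position for s in ts.sites()]) / ts.sequence_length
    return HaplotypeAlignment(geno, positions, locus_length_bp=L_bp,
                              scenario_id=scenario_id)


class MsprimeEngine:
    """Reference coalescent engine: dispatches scenarios to msprime.

    Simulations use continuous (infinite-sites) coordinates and a binary
    0/1 mutation model, so every site is biallelic with known ancestral
    state — the conventions of ms-style simulators. Deterministic given
    (scenario, n_chroms, seed).
    """

    def simulate(self, scenario, n_chroms: int, seed: int) -> HaplotypeAlignment:
        seed = int(seed)
        if seed < 1:
            raise ValueError("msprime seeds must be >= 1")
        if isinstance(scenario, RecombScenario):
            return self._constant(scenario.N, scenario.mu, scenario.r,
                                  scenario.L_bp, n_chroms, seed)
        if isinstance(scenario, ConstantThetaScenario):
            N = 10_000.0
            mu = scenario.theta / (4.0 * N * scenario.L_bp)
            r = scenario.rho_per_bp / (4.0 * N)
            return self._constant(N, mu, r, scenario.L_bp, n_chroms, seed)
        if isinstance(scenario, DemographicModel3Epoch):
            return self._three_epoch(scenario, n_chroms, seed)
        if isinstance(scenario, IntrogressionModel):
            return self._introgression(scenario, seed)
        if isinstance(scenario, SweepScenario):
            return self._sweep(scenario, n_chroms, seed)
        raise TypeError(f"unsupported scenario type {type(scenario).__name__}")

    # individual scenario families ---------------------------------------
    def _finish(self, ts, mu, seed, L_bp, scenario_id):
        mts = msprime.sim_mutations(ts, rate=mu, model=msprime.BinaryMutationModel(),
                                    discrete_genome=False, random_seed=seed + 1)
        return _alignment_from_ts(mts, L_bp, scenario_id)

    def _constant(self, N, mu, r, L_bp, n_chroms, seed):
        ts = msprime.sim_ancestry(
            samples=[msprime.SampleSet(n_chroms, ploidy=1)], ploidy=2,
            population_size=N, sequence_length=L_bp,
            recombination_rate=r, discrete_genome=False, random_seed=seed)
        return self._finish(ts, mu, seed, L_bp, "constant")

    def _three_epoch(self, m: DemographicModel3Epoch, n_chroms, seed):
        dem = msprime.Demography()
        dem.add_population(initial_size=m.N0)
        dem.add_population_parameters_change(time=m.T1, initial_size=m.N1)
        dem.add_population_parameters_change(time=m.T2, initial_size=m.N2)
        ts = msprime.sim_ancestry(
            samples=[msprime.SampleSet(n_chroms, ploidy=1)], ploidy=2,
            demography=dem, sequence_length=m.L_bp,
            recombination_rate=m.r, discrete_genome=False, random_seed=seed)
        return self._finish(ts, m.mu, seed, m.L_bp, "three_epoch")

    def _introgression(self, m: IntrogressionModel, seed):
        dem = msprime.Demography()
        dem.add_population(name="species1", initial_size=m.N1)
        dem.add_population(name="species2", initial_size=m.N2)
        dem.add_population(name="ancestral", initial_size=m.N_anc)
        # a forward-time pulse from A into B moves B's lineages to A
        # backward in time
        if m.direction == 1:
            dem.add_mass_migration(time=m.T_mig, source="species2",
                                   dest="species1", proportion=m.mig_prob)
        elif m.direction == 2:
            dem.add_mass_migration(time=m.T_mig, source="species1",
                                   dest="species2", proportion=m.mig_prob)
        elif m.direction != 0:
            raise ValueError("direction must be 0, 1 or 2")
        dem.add_population_split(time=m.T_split, derived=["species1", "species2"],
                                 ancestral="ancestral")
        ts = msprime.sim_ancestry(
            samples=[msprime.SampleSet(m.n1, population="species1", ploidy=1),
                     msprime.SampleSet(m.n2, population="species2", ploidy=1)],
            ploidy=2, demography=dem,
            sequence_length=m.L_bp, recombination_rate=m.r, discrete_genome=False,
            random_seed=seed)
        return self._finish(ts, m.mu, seed, m.L_bp, f"introgression_{m.direction}")

    def _sweep(self, sc: SweepScenario, n_chroms, seed):
        if sc.sweep_class not in SweepScenario.CLASSES:
            raise ValueError(f"unknown sweep class {sc.sweep_class!r}")
        L_total = 3 * sc.window_bp
        dem = msprime.Demography()
        dem.add_population(initial_size=sc.size_history[0][1])
        for t, size in sc.size_history[1:]:
            dem.add_population_parameters_change(time=t, initial_size=size)
        if sc.sweep_class == "neutral":
            model = None
        else:
            if sc.sweep_class in ("hard", "soft"):
                pos = 1.5 * sc.window_bp
            else:
                pos = (0.5 if sc.linked_side == 0 else 2.5) * sc.window_bp
            N_now = sc.size_history[0][1]
            if sc.sweep_class in ("hard", "linked_hard"):
                start = 1.0 / (2.0 * N_now)
            elif sc.soft_start_freq is not None:
                start = sc.soft_start_freq
            else:  # soft: selection on standing variation at appreciable frequency
                start = 0.5 * (sc.soft_freq_range[0] + sc.soft_freq_range[1])
            model = msprime.SweepGenicSelection(
                position=pos, start_frequency=start,
                end_frequency=1.0 - 1.0 / (2.0 * N_now), s=sc.s, dt=1e-6)
        kwargs = dict(samples=[msprime.SampleSet(n_chroms, ploidy=1)], ploidy=2,
                      demography=dem,
                      sequence_length=L_total, recombination_rate=sc.r,
                      discrete_genome=False, random_seed=seed)
        if model is not None:
            kwargs["model"] = [model, msprime.StandardCoalescent()]
        ts = msprime.sim_ancestry(**kwargs)
        full = self._finish(ts, sc.mu, seed, L_total, f"sweep_{sc.sweep_class}")
        return _crop_window(full, 1.0 / 3.0, 2.0 / 3.0, sc.window_bp,
                            scenario_id=full.scenario_id)


def _crop_window(aln: HaplotypeAlignment, lo: float, hi: float, window_bp: int,
                 scenario_id: str = "") -> HaplotypeAlignment:
    """Keep sites with position in [lo, hi) and rescale positions to [0, 1]."""
    keep = (aln.positions >= lo) & (aln.positions < hi)
    positions = (aln.positions[keep] - lo) / (hi - lo)
    return HaplotypeAlignment(aln.alleles[:, keep], positions,
                              locus_length_bp=window_bp, scenario_id=scenario_id)


DEFAULT_ENGINE = MsprimeEngine()


def simulate_alignment(scenario, n_chroms: int, engine=None,
                       seed: int = 1) -> HaplotypeAlignment:
    """Draw one alignment from the scenario's coalescent distribution."""
    engine = engine or DEFAULT_ENGINE
    try:
        return engine.simulate(scenario, n_chroms, seed)
    except Exception as exc:  # re-raise with scenario context
        raise RuntimeError(f"engine failure for scenario {scenario!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# autotetraploid read-fraction simulator


@dataclass
class ReadFractionMatrix:
    """Per-site, per-individual derived-read fractions R/C (sites x individuals)."""

    fractions: np.ndarray
    coverage_lambda: float
    group_map: np.ndarray  # chromosome index -> individual index


def make_tetraploid_reads(aln: HaplotypeAlignment, coverage_lambda: float = 25.0,
                          rng: np.random.Generator | None = None) -> ReadFractionMatrix:
    """Collapse phased chromosomes into autotetraploid read-pileup fractions.

    Chromosomes are randomly partitioned into groups of four (one synthetic
    tetraploid each). At each site the group's derived-allele dosage x in
    {0, .25, .5, .75, 1} parameterizes reads: coverage C ~ Poisson(lambda),
    redrawn if 0, and derived reads R ~ Binomial(C, x); the matrix entry is
    R/C. Homozygous sites are exactly 0 or 1; no sequencing error is
    simulated.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = aln.n_chroms
    if n % 4 != 0:
        raise ValueError(f"n_chroms={n} is not divisible by 4")
    n_ind = n // 4
    perm = rng.permutation(n)
    group_map = np.empty(n, dtype=np.int64)
    group_map[perm] = np.repeat(np.arange(n_ind), 4)
    # dosage x: sites x individuals
    x = np.zeros((aln.n_sites, n_ind))
    for ind in range(n_ind):
        x[:, ind] = aln.alleles[group_map == ind, :].sum(axis=0) / 4.0
    cov = rng.poisson(coverage_lambda, size=x.shape)
    while np.any(cov == 0):  # zero-coverage draws are redrawn
        zero = cov == 0
        cov[zero] = rng.poisson(coverage_lambda, size=int(zero.sum()))
    reads = rng.binomial(cov, x)
    return ReadFractionMatrix(fractions=reads / cov, coverage_lambda=coverage_lambda,
                              group_map=group_map)


# ---------------------------------------------------------------------------
# labeled datasets


@dataclass
class LabeledDataset:
    """Network-ready split: images, positional features, labels."""

    images: np.ndarray  # (N, a, b) float32
    positions: np.ndarray | None  # (N, P) float32 or None
    labels: np.ndarray  # (N,) int class indices or (N, D) float responses
    split: str = "train"
    class_names: list[str] | None = None
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.labels)

    def class_counts(self) -> np.ndarray:
        if self.labels.ndim != 1:
            raise ValueError("class_counts applies to classification labels")
        k = len(self.class_names) if self.class_names else int(self.labels.max()) + 1
        return np.bincount(self.labels.astype(int), minlength=k)

    def one_hot(self) -> np.ndarray:
        k = len(self.class_names) if self.class_names else int(self.labels.max()) + 1
        out = np.zeros((self.n, k), dtype=np.float32)
        out[np.arange(self.n), self.labels.astype(int)] = 1.0
        return out

    def inputs(self) -> list[np.ndarray]:
        return [self.images] if self.positions is None else [self.images, self.positions]

    def save(self, path) -> None:
        import json

        np.savez_compressed(
            path, images=self.images,
            positions=self.positions if self.positions is not None else np.zeros(0),
            labels=self.labels,
            meta=np.frombuffer(json.dumps({
                "split": self.split, "class_names": self.class_names,
                "config": self.config, "has_positions": self.positions is not None,
            }).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "LabeledDataset":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            return cls(images=z["images"],
                       positions=z["positions"] if meta["has_positions"] else None,
                       labels=z["labels"], split=meta["split"],
                       class_names=meta["class_names"], config=meta["config"])


def _prepare(alignments, labels, width, *, sort, transpose, encoding,
             position_mode, split, class_names=None, config=None,
             matrices=None) -> LabeledDataset:
    """Encode/sort/pad/transpose a list of alignments into a LabeledDataset.

    ``matrices`` overrides the allele matrices (used for read-fraction
    inputs, which are already real-valued and are padded with zeros).
    """
    images, posfeats = [], []
    for i, aln in enumerate(alignments):
        mat = matrices[i] if matrices is not None else encode_alleles(aln.alleles, encoding)
        img, pos = pad_and_shape(mat, aln.positions, width, sort=sort,
                                 transpose=transpose, encoding=encoding,
                                 name=aln.scenario_id)
        images.append(img.pixels)
        if position_mode == PositionFeature.DISTANCES:
            posfeats.append(positions_to_distances(aln.positions, width - 1).values)
        elif position_mode == PositionFeature.POSITIONS:
            posfeats.append(pos.values)
    labels = np.asarray(labels)
    return LabeledDataset(
        images=np.stack(images).astype(np.float32),
        positions=np.stack(posfeats).astype(np.float32) if position_mode else None,
        labels=labels, split=split, class_names=class_names,
        config=dict(config or {}, width=width, sort=sort, transpose=transpose,
                    encoding=encoding, position_mode=position_mode))


def _max_sites(groups) -> int:
    return max((a.n_sites for alns in groups for a in alns), default=1)


# --- theta toy --------------------------------------------------------------


def simulate_theta_toy(rng, n_examples: int, n_chroms: int = 40,
                       theta_range=(10.0, 50.0), engine=None):
    """Constant-size panmictic alignments with theta ~ U(10, 50)."""
    engine = engine or DEFAULT_ENGINE
    alignments, thetas = [], []
    for _ in range(n_examples):
        theta = float(rng.uniform(*theta_range))
        seed = int(rng.integers(1, 2**31 - 2))
        alignments.append(simulate_alignment(
            ConstantThetaScenario(theta=theta), n_chroms, engine, seed))
        thetas.append(theta)
    return alignments, np.array(thetas)


def build_theta_toy_dataset(rng, n_train: int = 4000, n_val: int = 500,
                            n_test: int = 1000, sort: bool = True,
                            transpose: bool = True, engine=None) -> dict:
    """Train/val/test splits for the theta-regression toy task."""
    splits = {}
    raw = {}
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        raw[split] = simulate_theta_toy(rng, n, engine=engine)
    width = _max_sites([alns for alns, _ in raw.values()])
    for split, (alns, thetas) in raw.items():
        splits[split] = _prepare(alns, thetas, width, sort=sort, transpose=transpose,
                                 encoding=Encoding.ZERO_ONE, position_mode=None,
                                 split=split, config={"task": "theta_toy"})
    return splits


# --- recombination ----------------------------------------------------------


def build_rho_dataset(rng, n_train: int = 10_000, n_val: int = 500,
                      n_test: int = 1000, tetraploid: bool = False,
                      interpolation_test: bool = False, n_chroms: int | None = None,
                      coverage_lambda: float = 25.0, engine=None) -> dict:
    """Recombination-rate datasets (phased haplotype or autotetraploid).

    Labels are rho per bp (4*N*r). The haploid task samples 50 chromosomes;
    the tetraploid task samples 48 chromosomes, collapsed to 12 read-
    fraction individuals. ``interpolation_test`` draws the *test* split
    from the held-out population sizes {30,35,40,45}k.
    """
    engine = engine or DEFAULT_ENGINE
    if n_chroms is None:
        n_chroms = 48 if tetraploid else 50
    raw = {}
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        alns, rhos, fracs = [], [], []
        for _ in range(n):
            if split == "test" and interpolation_test:
                sc = draw_interpolation_scenario(rng)
            else:
                sc = draw_recomb_scenario(rng)
            seed = int(rng.integers(1, 2**31 - 2))
            aln = simulate_alignment(sc, n_chroms, engine, seed)
            alns.append(aln)
            rhos.append(sc.rho_per_bp)
            if tetraploid:
                fracs.append(make_tetraploid_reads(aln, coverage_lambda, rng))
        raw[split] = (alns, np.array(rhos), fracs)
    width = _max_sites([alns for alns, _, _ in raw.values()])
    splits = {}
    for split, (alns, rhos, fracs) in raw.items():
        matrices = [f.fractions.T.astype(np.float32) for f in fracs] if tetraploid else None
        splits[split] = _prepare(
            alns, rhos, width, sort=True, transpose=True,
            encoding=Encoding.ZERO_ONE, position_mode=PositionFeature.POSITIONS,
            split=split, matrices=matrices,
            config={"task": "rho_tetraploid" if tetraploid else "rho_haploid",
                    "interpolation_test": interpolation_test})
    return splits


# --- introgression -----------------------------------------------------------

INTROGRESSION_DEFAULTS = IntrogressionModel()
INTROGRESSION_CLASSES = ["no_introgression", "species1_to_species2",
                         "species2_to_species1"]
# published train composition: 107,500 / 107,500 / 7,500
INTROGRESSION_TRAIN_RATIO = (107_500, 107_500, 7_500)


def build_introgression_dataset(rng, model: IntrogressionModel | None = None,
                                n_train=(107_500, 107_500, 7_500),
                                n_val_per_class: int = 2_500,
                                n_test_per_class: int = 2_500,
                                engine=None) -> dict:
    """Three-class introgression splits.

    The training split is deliberately imbalanced (easy donor-direction
    class undersampled); validation and test splits are exactly balanced
    so accuracy estimates are unbiased. Chromosomes stay grouped by
    species (no similarity sorting across species blocks).
    """
    engine = engine or DEFAULT_ENGINE
    model = model or INTROGRESSION_DEFAULTS
    raw = {}
    for split, counts in (("train", tuple(n_train)),
                          ("val", (n_val_per_class,) * 3),
                          ("test", (n_test_per_class,) * 3)):
        alns, labels = [], []
        for direction, n in enumerate(counts):
            sc = replace(model, direction=direction)
            for _ in range(n):
                seed = int(rng.integers(1, 2**31 - 2))
                alns.append(simulate_alignment(sc, 0, engine, seed))
                labels.append(direction)
        raw[split] = (alns, np.array(labels, dtype=np.int64))
    width = _max_sites([alns for alns, _ in raw.values()])
    splits = {}
    for split, (alns, labels) in raw.items():
        splits[split] = _prepare(alns, labels, width, sort=False, transpose=True,
                                 encoding=Encoding.ZERO_ONE, position_mode=None,
                                 split=split, class_names=INTROGRESSION_CLASSES,
                                 config={"task": "introgression"})
    return splits


# --- sweeps -----------------------------------------------------------------

SWEEP_DEFAULTS = SweepScenario()
SWEEP_CLASSES = list(SweepScenario.CLASSES)
# published (approximate) train composition over
# (hard, soft, linked_hard, linked_soft, neutral)
SWEEP_TRAIN_FRACTIONS = (0.17, 0.17, 0.265, 0.265, 0.13)


def _sweep_counts(total: int, fractions=SWEEP_TRAIN_FRACTIONS) -> list[int]:
    counts = [int(round(total * f)) for f in fractions]
    counts[-1] += total - sum(counts)
    return counts


def build_sweep_dataset(rng, scenario: SweepScenario | None = None,
                        n_train_total: int = 233_655, n_val_per_class: int = 400,
                        n_test_per_class: int = 600, n_chroms: int = 208,
                        max_segsites: int = 5_000, s_range=(0.03, 0.1),
                        engine=None) -> dict:
    """Five-class sweep splits with the rebalanced training composition.

    Training examples follow the ~13% neutral / 17% hard / 17% soft /
    26.5% linked-hard / 26.5% linked-soft mixture; validation and test are
    balanced. Replicates with more than ``max_segsites`` segregating sites
    are discarded and re-simulated. Selection coefficients are drawn
    uniformly from ``s_range`` per replicate.
    """
    engine = engine or DEFAULT_ENGINE
    base = scenario or SWEEP_DEFAULTS
    raw = {}
    for split, counts in (
        ("train", _sweep_counts(n_train_total)),
        ("val", [n_val_per_class] * 5),
        ("test", [n_test_per_class] * 5),
    ):
        alns, labels = [], []
        for cls_idx, cls in enumerate(SWEEP_CLASSES):
            done = failures = 0
            while done < counts[cls_idx]:
                sc = replace(base, sweep_class=cls,
                             s=float(rng.uniform(*s_range)),
                             linked_side=int(rng.integers(0, 2)),
                             soft_start_freq=float(rng.uniform(*base.soft_freq_range)))
                seed = int(rng.integers(1, 2**31 - 2))
                try:
                    aln = simulate_alignment(sc, n_chroms, engine, seed)
                except RuntimeError:
                    # a weakly selected sweep can outlast the constant-size
                    # epoch the engine requires; redraw the scenario
                    failures += 1
                    if failures > 20 + 2 * counts[cls_idx]:
                        raise
                    continue
                if aln.n_sites > max_segsites:
                    continue  # published filter: keep replicates with <= 5,000 sites
                alns.append(aln)
                labels.append(cls_idx)
                done += 1
        raw[split] = (alns, np.array(labels, dtype=np.int64))
    width = _max_sites([alns for alns, _ in raw.values()])
    splits = {}
    for split, (alns, labels) in raw.items():
        splits[split] = _prepare(alns, labels, width, sort=True, transpose=True,
                                 encoding=Encoding.ZERO_ONE,
                                 position_mode=PositionFeature.POSITIONS,
                                 split=split, class_names=SWEEP_CLASSES,
                                 config={"task": "sweeps"})
    return splits


# --- demography ---------------------------------------------------------------


def simulate_demography(rng, n_examples: int, ranges=None, n_chroms: int = 50,
                        engine=None, **model_kwargs):
    """Three-epoch alignments with uniform parameter draws; labels are the
    (N0, N1, N2, T1, T2) vectors."""
    engine = engine or DEFAULT_ENGINE
    alignments, labels = [], []
    for _ in range(n_examples):
        m = draw_demographic_model(rng, ranges, **model_kwargs)
        seed = int(rng.integers(1, 2**31 - 2))
        alignments.append(simulate_alignment(m, n_chroms, engine, seed))
        labels.append(m.label())
    return alignments, np.vstack(labels)


def build_demography_dataset(rng, ranges=None, n_train: int = 80_000,
                             n_val: int = 10_000, n_test: int = 10_000,
                             n_chroms: int = 50, sort: bool = True,
                             encoding: str = Encoding.ZERO_255,
                             engine=None, **model_kwargs) -> dict:
    """Five-parameter demographic regression splits with distance-vector
    position features (length = max segregating sites - 1)."""
    raw = {}
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        raw[split] = simulate_demography(rng, n, ranges, n_chroms, engine,
                                         **model_kwargs)
    width = _max_sites([alns for alns, _ in raw.values()])
    splits = {}
    for split, (alns, labels) in raw.items():
        splits[split] = _prepare(alns, labels, width, sort=sort, transpose=True,
                                 encoding=encoding,
                                 position_mode=PositionFeature.DISTANCES,
                                 split=split, config={"task": "demography"})
    return splits
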