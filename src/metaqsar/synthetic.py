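"""Synthetic QSAR-collection generator.

Generates collections of QSAR problems with the statistical structure the
meta-learning analysis assumes, so the full pipeline can be exercised and
tested without any external download:

* a six-level target class hierarchy, with targets attached to leaves;
* per target, an amino-acid sequence whose residue composition is biased by
  its L1 class (so sequence-derived meta-features carry family signal), a
  preferred-name group label, and an activity-generating *mechanism*;
* per target, a binary fingerprint table (complete), a continuous
  all-descriptor table with injected missingness, and its basic-descriptor
  column subset;
* bioactivities on a pIC50-like log scale (roughly 4-10) produced by one of
  three mechanisms chosen so that different learner families win on
  different target families (the "planted winner" construction):

  ``linear-descriptor``
      sparse linear form on a few descriptors - linear learners near-optimal;
  ``substructure-rule``
      indicator effects plus pairwise interactions on specific fingerprint
      bits - tree ensembles on fingerprints near-optimal;
  ``smooth-nonlinear``
      smooth sinusoids of random projections of a few descriptors - RBF
      kernel methods near-optimal.

No attempt is made at realistic chemistry: there are no molecules behind the
fingerprints and descriptors, and the mechanisms are stand-ins, not a model
of real bioactivity databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Collection
from .hierarchy import N_LEVELS, ClassHierarchy

MECHANISMS = ("linear-descriptor", "substructure-rule", "smooth-nonlinear")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _default_mix() -> dict[str, float]:
    return {m: 1.0 / len(MECHANISMS) for m in MECHANISMS}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic collection.

    Defaults are the desk scale: 60 targets of 80-300 compounds, 128
    fingerprint bits, 16 basic within 64 total descriptors - small enough
    for the full pipeline to run in minutes on one CPU while keeping the
    structure of the emulated data (10-6000 compounds per target, 43/1447
    descriptors, 1024 bits at full scale).

    Parameters
    ----------
    mechanism_mix : dict
        Probability of each activity mechanism. With
        ``condition_on_l1=True`` (default) the mechanism is instead a
        deterministic function of the L1 class, realised so the collection
        mechanism shares follow the mix; this makes "which learner wins"
        predictable from the target family.
    noise_sd : float
        Gaussian noise on the log-activity scale. 0.5 log units, the order
        of inter-assay reproducibility of heterogeneous potency data.
    hierarchy_shape : tuple
        Branching factor per level under the virtual root (6 levels).
    """

    n_targets: int = 60
    compounds_range: tuple[int, int] = (80, 300)
    n_fp_bits: int = 128
    n_basic_desc: int = 16
    n_all_desc: int = 64
    missing_rate: float = 0.05
    noise_sd: float = 0.5
    mechanism_mix: dict[str, float] = field(default_factory=_default_mix)
    hierarchy_shape: tuple[int, ...] = (3, 2, 2, 1, 1, 1)
    seq_length_range: tuple[int, int] = (100, 600)
    condition_on_l1: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mechanism_mix.values()) - 1.0) > 1e-9:
            raise ValueError("mechanism_mix probabilities must sum to 1")
        unknown = set(self.mechanism_mix) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanism(s): {sorted(unknown)}")
        lo, hi = self.compounds_range
        if not (10 <= lo <= hi <= 6000):
            raise ValueError("compounds_range must lie within [10, 6000]")
        if self.n_basic_desc > self.n_all_desc:
            raise ValueError("n_basic_desc must not exceed n_all_desc")
        if len(self.hierarchy_shape) != N_LEVELS:
            raise ValueError(f"hierarchy_shape needs {N_LEVELS} branching factors")
        if any(b < 1 for b in self.hierarchy_shape):
            raise ValueError("hierarchy branching factors must be >= 1")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_targets": self.n_targets,
            "compounds_range": list(self.compounds_range),
            "n_fp_bits": self.n_fp_bits,
            "n_basic_desc": self.n_basic_desc,
            "n_all_desc": self.n_all_desc,
            "missing_rate": self.missing_rate,
            "noise_sd": self.noise_sd,
            "mechanism_mix": dict(self.mechanism_mix),
            "hierarchy_shape": list(self.hierarchy_shape),
            "seq_length_range": list(self.seq_length_range),
            "condition_on_l1": self.condition_on_l1,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("compounds_range", "hierarchy_shape", "seq_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTarget:
    """One generated protein target with its ground-truth mechanism."""

    target_id: str
    sequence: str
    class_path: tuple[str, ...]
    preferred_name: str
    mechanism: str
    ground_truth_params: dict


@dataclass
class CompoundTables:
    """Raw compound tables for one target.

    ``descriptors`` holds the complete (pre-missingness) all-descriptor
    table the activity mechanism is evaluated on; ``all_missing`` is the
    same table with missing cells injected, and ``basic_missing`` its
    basic-descriptor column subset.
    """

    fp: pd.DataFrame
    descriptors: pd.DataFrame
    all_missing: pd.DataFrame
    basic_missing: pd.DataFrame


def generate_hierarchy(config: SyntheticConfig) -> ClassHierarchy:
    """Build the class tree described by ``config.hierarchy_shape``.

    Labels encode their path (``L2.0.1`` is child 1 of L1 class 0), every
    leaf has depth 6 under the virtual root, and the number of leaves is the
    product of the branching factors.
    """
    paths: list[tuple[tuple[str, ...], tuple[int, ...]]] = [((), ())]
    for level, branching in enumerate(config.hierarchy_shape, start=1):
        grown = []
        for labels, idxs in paths:
            for i in range(branching):
                child_idxs = idxs + (i,)
                label = f"L{level}." + ".".join(map(str, child_idxs))
                grown.append((labels + (label,), child_idxs))
        paths = grown
    return ClassHierarchy(leaves=[labels for labels, _ in paths])


def _l1_index(leaf: tuple[str, ...]) -> int:
    return int(leaf[0].split(".")[1])


def _residue_profile(l1_index: int) -> np.ndarray:
    """Class-specific residue frequencies: each L1 class up-weights a
    disjoint block of residues, giving composition meta-features family
    signal."""
    n = len(AMINO_ACIDS)
    weights = np.ones(n)
    block = 6
    start = (l1_index * block) % n
    for offset in range(block):
        weights[(start + offset) % n] = 4.0
    return weights / weights.sum()


def generate_target(
    config: SyntheticConfig,
    class_leaf: tuple[str, ...],
    rng: np.random.Generator,
    target_id: str = "T0000",
) -> SyntheticTarget:
    """Generate one target attached to ``class_leaf``.

    The mechanism is sampled from ``mechanism_mix`` - or, when
    ``condition_on_l1`` is set, chosen deterministically from the L1 class
    so that the best learner family depends on the target family. Ground
    truth coefficients for the mechanism are drawn here and recorded so
    recovery tests can check selections against them.
    """
    l1 = _l1_index(class_leaf)
    if config.condition_on_l1:
        active = [m for m in MECHANISMS if config.mechanism_mix.get(m, 0) > 0]
        mechanism = active[l1 % len(active)]
    else:
        names = list(config.mechanism_mix)
        probs = np.array([config.mechanism_mix[m] for m in names])
        mechanism = names[rng.choice(len(names), p=probs)]

    lo, hi = config.seq_length_range
    length = int(rng.integers(lo, hi + 1))
    profile = _residue_profile(l1)
    sequence = "".join(
        AMINO_ACIDS[i] for i in rng.choice(len(AMINO_ACIDS), size=length, p=profile)
    )
    preferred_name = f"pn-{l1}-{int(rng.integers(0, max(2, config.n_targets // 8)))}"

    params: dict = {"intercept": float(rng.uniform(5.5, 7.0))}
    if mechanism == "linear-descriptor":
        k = min(8, config.n_all_desc)
        idx = rng.choice(config.n_all_desc, size=k, replace=False)
        coef = rng.normal(0.0, 1.0, size=k)
        coef /= np.linalg.norm(coef)
        params.update(descriptor_idx=idx.tolist(), coef=coef.tolist())
    elif mechanism == "substructure-rule":
        k = min(6, config.n_fp_bits)
        bits = rng.choice(config.n_fp_bits, size=k, replace=False)
        weights = rng.uniform(0.6, 1.2, size=k) * rng.choice([-1.0, 1.0], size=k)
        n_pairs = min(3, k // 2)
        pair_idx = rng.choice(k, size=(n_pairs, 2), replace=False)
        pair_w = rng.uniform(0.8, 1.6, size=n_pairs) * rng.choice([-1.0, 1.0], n_pairs)
        params.update(
            bits=bits.tolist(),
            weights=weights.tolist(),
            pairs=[[int(bits[i]), int(bits[j])] for i, j in pair_idx],
            pair_weights=pair_w.tolist(),
        )
    elif mechanism == "smooth-nonlinear":
        # Gaussian bumps in standardized descriptor space; centres are
        # picked among the target's own compounds at activity time so the
        # surface curves where the data actually lie, and the length scale
        # matches typical inter-compound distances (RBF-representable).
        n_bumps = 6
        params.update(
            n_bumps=n_bumps,
            amplitudes=(
                rng.uniform(1.0, 2.0, size=n_bumps)
                * rng.choice([-1.0, 1.0], size=n_bumps)
            ).tolist(),
            length_scale_sq=config.n_all_desc / 2.0,
        )
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown mechanism {mechanism!r}")

    return SyntheticTarget(
        target_id=target_id,
        sequence=sequence,
        class_path=tuple(class_leaf),
        preferred_name=preferred_name,
        mechanism=mechanism,
        ground_truth_params=params,
    )


def generate_compounds(
    target: SyntheticTarget,
    n_compounds: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    folds: int = 10,
) -> CompoundTables:
    """Generate the fingerprint and descriptor tables for one target.

    Fingerprint bit probabilities are drawn per target from a Beta
    distribution so aggregated-fingerprint meta-features vary between
    targets. Missingness is injected into descriptor tables only;
    fingerprint tables are always complete. The basic table is a column
    subset of the all-descriptor table.
    """
    if n_compounds < 10:
        raise ValueError("need at least 10 compounds per target")
    if n_compounds < 2 * folds:
        raise ValueError(
            f"{n_compounds} compounds cannot support {folds}-fold cross-validation"
        )
    compound_ids = pd.Index(
        [f"{target.target_id}_c{i:04d}" for i in range(n_compounds)],
        name="compound_id",
    )

    bit_p = rng.beta(0.9, 3.0, size=config.n_fp_bits)
    fp = pd.DataFrame(
        (rng.random((n_compounds, config.n_fp_bits)) < bit_p).astype(np.int64),
        index=compound_ids,
        columns=[f"bit{j:04d}" for j in range(config.n_fp_bits)],
    )

    loc = rng.normal(0.0, 2.0, size=config.n_all_desc)
    scale = rng.uniform(0.5, 2.0, size=config.n_all_desc)
    desc = pd.DataFrame(
        loc + scale * rng.normal(size=(n_compounds, config.n_all_desc)),
        index=compound_ids,
        columns=[f"d{j:04d}" for j in range(config.n_all_desc)],
    )

    all_missing = desc.copy()
    if config.missing_rate > 0:
        mask = rng.random(desc.shape) < config.missing_rate
        # keep at least one observed value per column so imputation is defined
        full_cols = mask.all(axis=0)
        mask[0, full_cols] = False
        all_missing = desc.mask(mask)
    basic_missing = all_missing.iloc[:, : config.n_basic_desc]
    return CompoundTables(
        fp=fp, descriptors=desc, all_missing=all_missing, basic_missing=basic_missing
    )


def generate_activities(
    target: SyntheticTarget,
    compounds: CompoundTables,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Evaluate the target's mechanism on its compounds and add noise.

    Descriptor-based signals are standardised to unit spread so the
    log-activity scale (intercept ~ 6, signal sd ~ 1, plus ``noise_sd``)
    lands in the 4-10 range regardless of descriptor units. The
    substructure mechanism is left on its natural scale: its indicator
    weights are already of order one, and rescaling would distort the exact
    step sizes the rule encodes.
    """
    p = target.ground_truth_params
    mech = target.mechanism
    if mech == "linear-descriptor":
        X = compounds.descriptors.iloc[:, p["descriptor_idx"]].to_numpy()
        Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        signal = Xz @ np.asarray(p["coef"])
        sd = signal.std()
        if sd > 0:
            signal = signal / sd
    elif mech == "substructure-rule":
        bits = np.asarray(p["bits"])
        B = compounds.fp.iloc[:, bits].to_numpy(dtype=float)
        signal = B @ np.asarray(p["weights"])
        for (a, b), w in zip(p["pairs"], p["pair_weights"]):
            signal = signal + w * (
                compounds.fp.iloc[:, a].to_numpy() * compounds.fp.iloc[:, b].to_numpy()
            )
        signal = signal - signal.mean()
    elif mech == "smooth-nonlinear":
        X = compounds.descriptors.to_numpy()
        Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        centers = rng.choice(len(Xz), size=min(p["n_bumps"], len(Xz)), replace=False)
        p["center_compounds"] = [str(compounds.fp.index[c]) for c in centers]
        signal = np.zeros(len(Xz))
        for c, a in zip(centers, p["amplitudes"]):
            sq_dist = ((Xz - Xz[c]) ** 2).sum(axis=1)
            signal = signal + a * np.exp(-sq_dist / (2.0 * p["length_scale_sq"]))
        sd = signal.std()
        if sd > 0:
            signal = (signal - signal.mean()) / sd
    else:
        raise ValueError(f"unknown mechanism {mech!r}")

    y = p["intercept"] + signal + rng.normal(0.0, config.noise_sd, size=len(signal))
    return pd.Series(y, index=compounds.fp.index, name="activity")


def generate_collection(config: SyntheticConfig) -> Collection:
    """Generate a full collection: hierarchy, targets, tables, activities.

    Deterministic given the configuration (including its seed): targets get
    independent child random streams spawned from the configured seed, and
    leaves are assigned round-robin so L1 classes - hence mechanisms, under
    ``condition_on_l1`` - are balanced.
    """
    hierarchy = generate_hierarchy(config)
    seedseq = np.random.SeedSequence(config.seed)
    streams = seedseq.spawn(config.n_targets)
    targets: dict[str, dict] = {}
    tables: dict[str, dict[str, pd.DataFrame]] = {}
    activities: dict[str, pd.Series] = {}
    # interleave leaves across L1 classes so consecutive targets rotate
    # through families and any prefix of the collection stays balanced
    by_l1: dict[int, list[tuple[str, ...]]] = {}
    for leaf in hierarchy.leaves:
        by_l1.setdefault(_l1_index(leaf), []).append(leaf)
    groups = [by_l1[k] for k in sorted(by_l1)]
    depth = max(len(g) for g in groups)
    leaves = [g[i % len(g)] for i in range(depth) for g in groups]
    for i in range(config.n_targets):
        rng = np.random.default_rng(streams[i])
        tid = f"T{i:04d}"
        leaf = leaves[i % len(leaves)]
        target = generate_target(config, leaf, rng, target_id=tid)
        n_compounds = int(rng.integers(*config.compounds_range))
        compounds = generate_compounds(target, n_compounds, config, rng)
        y = generate_activities(target, compounds, config, rng)
        hierarchy.attach(tid, leaf)
        targets[tid] = {
            "sequence": target.sequence,
            "preferred_name": target.preferred_name,
            "mechanism": target.mechanism,
        }
        tables[tid] = {
            "fp": compounds.fp,
            "basic": compounds.basic_missing,
            "all": compounds.all_missing,
        }
        activities[tid] = y
    return Collection(
        targets=targets,
        tables=tables,
        activities=activities,
        hierarchy=hierarchy,
        config=config.to_dict(),
    )
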