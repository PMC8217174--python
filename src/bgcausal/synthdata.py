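"""Synthetic multichannel BOLD-like series with known causal ground truth.

The generator emulates the block/subject design of the recording protocol: eight
named regions, 20 subjects, alternating 100-volume motor/resting blocks at a
1.6 s repetition time, temporal autocorrelation, an optional shared nuisance
component, and planted couplings at lags 0-2 of four kinds:

``linear``
    ``y_t += strength * x_{t-lag}`` (at lag 0: a shared latent innovation,
    recorded undirected in the ground truth).
``quadratic``
    ``y_t += strength * x_{t-lag}**2`` -- invisible to linear statistics when
    the source is symmetric about zero.
``threshold``
    ``y_t += strength * sign(x_{t-lag} - offset)`` -- a centered step.
``multiplicative_noise``
    ``y_t += strength * x_{t-lag} * eta_t`` with ``eta`` standard normal --
    dependence carried entirely by the noise amplitude, undetectable by
    correlation- or regression-based statistics.

Every region additionally follows an AR(1) innovation process with coefficient
``autocorr``. The linear part of a coupling set must be stable (spectral
radius of the companion matrix < 1) or generation is refused.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .core import Block, RegionSet, DEFAULT_REPETITION_TIME

COUPLING_KINDS = ("linear", "quadratic", "threshold", "multiplicative_noise")

__all__ = [
    "RegionSet",
    "CouplingSpec",
    "StudyDesign",
    "GroundTruthGraph",
    "Study",
    "generate_block",
    "generate_study",
    "add_nuisance",
    "write_study",
    "default_coupling_presets",
    "classification_fixture_presets",
]


@dataclass(frozen=True)
class CouplingSpec:
    """One planted dependence between two regions at a fixed lag."""

    source: str
    target: str
    lag: int
    kind: str = "linear"
    strength: float = 0.5
    offset: float = 0.0  # threshold kind only

    def __post_init__(self) -> None:
        if self.kind not in COUPLING_KINDS:
            raise ValueError(f"unknown coupling kind {self.kind!r}; one of {COUPLING_KINDS}")
        if self.lag < 0:
            raise ValueError("coupling lag must be >= 0")
        if self.lag == 0 and self.kind != "linear":
            raise ValueError(
                "lag-0 couplings are realized as shared latent innovations and "
                "support only kind='linear'"
            )

    def triple(self) -> tuple[str, str, int]:
        """Canonical (source, target, lag); lag-0 pairs are order-normalized."""
        if self.lag == 0 and self.target < self.source:
            return (self.target, self.source, 0)
        return (self.source, self.target, self.lag)


@dataclass(frozen=True)
class StudyDesign:
    """Block/subject layout of a recording session."""

    n_subjects: int = 20
    blocks_per_condition: int = 2
    block_length: int = 100
    repetition_time: float = DEFAULT_REPETITION_TIME
    conditions: tuple[str, ...] = ("motor", "resting")

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.blocks_per_condition < 1 or self.block_length < 1:
            raise ValueError("design counts must be positive")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ValueError("conditions must be unique and non-empty")

    @property
    def volumes_per_subject(self) -> int:
        return self.block_length * self.blocks_per_condition * len(self.conditions)

    @property
    def samples_per_condition(self) -> int:
        return self.block_length * self.blocks_per_condition * self.n_subjects


@dataclass(frozen=True)
class GroundTruthGraph:
    """The planted couplings of one condition, queryable as link triples."""

    links: tuple[CouplingSpec, ...]
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "links", tuple(self.links))

    def triples(self) -> set[tuple[str, str, int]]:
        return {c.triple() for c in self.links}

    def has_link(self, source: str, target: str, lag: int) -> bool:
        if lag == 0:
            key = (min(source, target), max(source, target), 0)
        else:
            key = (source, target, lag)
        return key in self.triples()

    def __contains__(self, triple: tuple[str, str, int]) -> bool:
        return self.has_link(*triple)


@dataclass
class Study:
    """Generated blocks plus the ground truth that produced them."""

    blocks: list[Block]
    graphs: dict[str, GroundTruthGraph]
    design: StudyDesign
    regions: RegionSet
    seed: int

    def condition_blocks(self, condition: str) -> list[Block]:
        return [b for b in self.blocks if b.condition == condition]


def _linear_companion_radius(regions: RegionSet, couplings, autocorr: float) -> float:
    """Spectral radius of the companion matrix of the linear lagged part."""
    n = regions.count
    max_lag = max([1] + [c.lag for c in couplings])
    mats = [np.zeros((n, n)) for _ in range(max_lag)]
    mats[0] += np.eye(n) * autocorr
    for c in couplings:
        if c.kind == "linear" and c.lag >= 1:
            mats[c.lag - 1][regions.index(c.target), regions.index(c.source)] += c.strength
    top = np.hstack(mats)
    bottom = np.hstack([np.eye(n * (max_lag - 1)), np.zeros((n * (max_lag - 1), n))])
    companion = np.vstack([top, bottom]) if max_lag > 1 else top
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def _innovations(rng, shape, distribution, scale):
    if distribution == "gaussian":
        return rng.standard_normal(shape) * scale
    if distribution == "uniform":  # unit-variance uniform
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=shape) * scale
    raise ValueError(f"unknown innovation distribution {distribution!r}")


def generate_block(
    region_set: RegionSet,
    couplings,
    block_length: int,
    noise_scale: float = 1.0,
    autocorr: float = 0.4,
    seed=None,
    innovation: str = "gaussian",
    burn_in: int = 300,
) -> np.ndarray:
    """Simulate one stationary block of the coupled autoregressive process.

    Returns a ``block_length x n_regions`` array. The first ``burn_in`` samples
    are simulated and discarded so the returned segment is (approximately) a
    draw from the stationary distribution. Identical seeds give identical
    output.
    """
    if seed is None:
        raise ValueError("generate_block requires an explicit seed")
    if block_length < 10:
        raise ValueError("block_length must be >= 10")
    couplings = list(couplings)
    for c in couplings:
        for lab in (c.source, c.target):
            if lab not in region_set:
                raise KeyError(f"coupling names unknown region {lab!r}")
    if not (0 <= abs(autocorr) < 1):
        raise ValueError("autocorr must satisfy |autocorr| < 1")
    radius = _linear_companion_radius(region_set, couplings, autocorr)
    if radius >= 1.0:
        raise ValueError(
            f"unstable coupling set: companion-matrix spectral radius {radius:.3f} >= 1"
        )

    rng = np.random.default_rng(seed)
    n = region_set.count
    n_tot = burn_in + block_length
    eps = _innovations(rng, (n_tot, n), innovation, noise_scale)

    # Contemporaneous couplings: a shared latent innovation added to both ends.
    for c in couplings:
        if c.lag == 0:
            z = rng.standard_normal(n_tot) * c.strength
            eps[:, region_set.index(c.source)] += z
            eps[:, region_set.index(c.target)] += z

    lagged = [c for c in couplings if c.lag >= 1]
    if not lagged:
        # Pure AR(1) channels: vectorized filter.
        x = signal.lfilter([1.0], [1.0, -autocorr], eps, axis=0)
        return x[burn_in:]

    mult_eta = {
        id(c): rng.standard_normal(n_tot)
        for c in lagged
        if c.kind == "multiplicative_noise"
    }
    terms = [
        (region_set.index(c.source), region_set.index(c.target), c.lag, c.kind,
         c.strength, c.offset, mult_eta.get(id(c)))
        for c in lagged
    ]
    x = np.zeros((n_tot, n))
    for t in range(n_tot):
        acc = eps[t].copy()
        if t >= 1:
            acc += autocorr * x[t - 1]
        for si, ti, lag, kind, s, off, eta in terms:
            if t < lag:
                continue
            xs = x[t - lag, si]
            if kind == "linear":
                acc[ti] += s * xs
            elif kind == "quadratic":
                acc[ti] += s * xs * xs
            elif kind == "threshold":
                acc[ti] += s * (1.0 if xs > off else -1.0)
            else:  # multiplicative_noise
                acc[ti] += s * xs * eta[t]
        x[t] = acc
    return x[burn_in:]


def _block_seed(master_seed: int, subject: int, condition_index: int, block_index: int):
    """Counter-keyed seed derivation: adding subjects or blocks never reshuffles
    the streams of earlier subjects."""
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(subject, condition_index, block_index)
    )


def generate_study(
    design: StudyDesign,
    graphs: dict[str, GroundTruthGraph],
    region_set: RegionSet | None = None,
    noise_scale: float = 1.0,
    autocorr: float = 0.4,
    seed: int = 0,
    innovation: str = "gaussian",
    burn_in: int = 300,
) -> Study:
    """Generate all blocks of a study, one ground-truth graph per condition."""
    region_set = region_set or RegionSet.default()
    for cond in design.conditions:
        if cond not in graphs:
            raise ValueError(f"missing ground-truth graph for condition {cond!r}")
    blocks: list[Block] = []
    for subject in range(design.n_subjects):
        for b in range(design.blocks_per_condition):
            # Conditions alternate within a session (motor -> resting -> ...).
            for ci, cond in enumerate(design.conditions):
                values = generate_block(
                    region_set,
                    graphs[cond].links,
                    design.block_length,
                    noise_scale=noise_scale,
                    autocorr=autocorr,
                    seed=_block_seed(seed, subject, ci, b),
                    innovation=innovation,
                    burn_in=burn_in,
                )
                blocks.append(
                    Block(values=values, regions=region_set, subject=subject,
                          condition=cond, index=b)
                )
    return Study(blocks=blocks, graphs=dict(graphs), design=design,
                 regions=region_set, seed=int(seed))


def add_nuisance(blocks, nuisance=None, weight: float = 1.0, seed=None):
    """Add a shared additive nuisance component (e.g. a physiological signal)
    to every region of every block.

    ``nuisance`` may be one 1-D series (applied to all blocks; lengths must
    match) or a list with one series per block. If omitted, a smooth AR(1)
    nuisance (coefficient 0.8) is drawn per block from ``seed``.

    Returns ``(contaminated_blocks, nuisance_series_per_block)``. The original
    blocks are recoverable by OLS regression against the returned series.
    """
    blocks = list(blocks)
    if nuisance is None:
        if seed is None:
            raise ValueError("either nuisance series or a seed must be given")
        rng = np.random.default_rng(seed)
        series = [
            signal.lfilter([1.0], [1.0, -0.8], rng.standard_normal(b.n_samples))
            for b in blocks
        ]
    elif isinstance(nuisance, (list, tuple)):
        series = [np.asarray(v, dtype=float) for v in nuisance]
        if len(series) != len(blocks):
            raise ValueError("one nuisance series per block required")
    else:
        series = [np.asarray(nuisance, dtype=float)] * len(blocks)
    out = []
    for b, s in zip(blocks, series):
        if len(s) != b.n_samples:
            raise ValueError(
                f"nuisance length {len(s)} != block length {b.n_samples}"
            )
        out.append(b.copy_with(b.values + weight * s[:, None]))
    return out, series


# ---------------------------------------------------------------------------
# Shipped presets
# ---------------------------------------------------------------------------

def default_coupling_presets(region_set: RegionSet | None = None) -> dict[str, GroundTruthGraph]:
    """Ground-truth graphs shipped as the package's default study conditions.

    A backbone of four permanent links (two instantaneous, two single-delayed,
    all linear) is shared by both conditions; each condition adds its own
    links, including one quadratic and one multiplicative-noise coupling so
    that all three dependence natures are represented. Strengths are chosen so
    the planted effects are comfortably detectable at the default study size
    (4,000 samples per condition).
    """
    region_set = region_set or RegionSet.default()
    permanent = [
        CouplingSpec("GPe", "STN", 0, "linear", 0.6),
        CouplingSpec("GPi", "SN", 0, "linear", 0.6),
        CouplingSpec("STN", "SN", 1, "linear", 0.5),
        CouplingSpec("SN", "M1", 1, "linear", 0.5),
    ]
    resting = permanent + [
        CouplingSpec("Tal", "M1", 1, "linear", 0.4),
        CouplingSpec("M1", "GPe", 1, "quadratic", 0.8),
        CouplingSpec("SN", "Put", 1, "multiplicative_noise", 1.0),
    ]
    motor = permanent + [
        CouplingSpec("M1", "SN", 1, "linear", 0.5),
        CouplingSpec("M1", "STN", 0, "linear", 0.5),
        CouplingSpec("Put", "M1", 2, "quadratic", 0.8),
    ]
    return {
        "resting": GroundTruthGraph(tuple(resting), "resting"),
        "motor": GroundTruthGraph(tuple(motor), "motor"),
    }


def classification_fixture_presets(region_set: RegionSet) -> dict[str, GroundTruthGraph]:
    """A compact fixture with one link of every nature and persistence class,
    on a reduced region set, for end-to-end classification checks.

    The strong linear links are permanent (their detection is near-certain per
    condition); the harder non-linear and complex links are condition-specific,
    where the persistence label only requires detection in their own condition.
    The quadratic strength sits in the regime where partial correlation keeps
    its nominal level while the distance-correlation statistic has high power.
    """
    permanent = [
        CouplingSpec("M1", "S1", 1, "linear", 0.7),
        CouplingSpec("Put", "GPe", 0, "linear", 0.8),
    ]
    resting = permanent + [
        CouplingSpec("Put", "S1", 2, "linear", 0.6),
        CouplingSpec("GPe", "SN", 1, "multiplicative_noise", 1.2),
    ]
    motor = permanent + [CouplingSpec("GPe", "M1", 1, "quadratic", 0.25)]
    return {
        "resting": GroundTruthGraph(tuple(resting), "resting"),
        "motor": GroundTruthGraph(tuple(motor), "motor"),
    }


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_study(study: Study, outdir, precision: int = 6) -> Path:
    """Write one TSV per subject x condition x block plus ground-truth and
    manifest JSON documents. Returns the manifest path."""
    from . import io as bio  # local import: io depends on core only

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for b in study.blocks:
        name = f"sub-{b.subject:02d}_{b.condition}_block-{b.index}.tsv"
        bio.write_table(b.values, study.regions.labels, outdir / name, precision=precision)
        entries.append(
            {"file": name, "subject": b.subject, "condition": b.condition,
             "block": b.index, "n_samples": b.n_samples}
        )
    truth = {
        cond: [
            {"source": c.source, "target": c.target, "lag": c.lag,
             "kind": c.kind, "strength": c.strength, "offset": c.offset}
            for c in g.links
        ]
        for cond, g in study.graphs.items()
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    manifest = {
        "design": {
            "n_subjects": study.design.n_subjects,
            "blocks_per_condition": study.design.blocks_per_condition,
            "block_length": study.design.block_length,
            "repetition_time": study.design.repetition_time,
            "conditions": list(study.design.conditions),
        },
        "regions": list(study.regions.labels),
        "seed": study.seed,
        "blocks": entries,
        "ground_truth": "ground_truth.json",
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
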