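"""Approximate Bayesian Computation for demographic inference.

The pipeline has two halves, mirroring the two shell commands built on it:

1. *Sampling* (:func:`abc_sample`): draw parameter vectors from a
   :class:`Prior`, simulate data under a demographic :class:`AbcModel`,
   summarise each simulated data set with a :class:`StatSet`, and stream
   the (parameters, statistics) rows to a tab-separated table on disk.
   Tables are never held in memory.

2. *Fitting* (:func:`abc_fit`): stream the table twice — first to estimate
   each statistic's standard deviation, then to compute standardised
   Euclidean distances to the observed vector — keep the closest
   ``ceil(tolerance * N)`` rows (rejection), and optionally apply the
   local-linear regression adjustment: a weighted regression of parameters
   on statistics over the accepted rows (Epanechnikov kernel on distance),
   shifting each accepted draw to the observed point.  Parameters with
   bounded support are adjusted on a transformed scale (log for positive
   scales, logit for rates) and back-transformed.

Six demographic models are pre-defined — SNM (standard neutral), SNMR
(neutral with recombination), PEMR (exponential growth with recombination),
BNM (bottleneck), IM (isolation with migration) and AM (ancient migration)
— plus a worked example of the user-model protocol (a double-domestication
scenario).  Two summary-statistic sets are provided: SDZ (S, Tajima's D and,
with an outgroup, Fay & Wu's H, averaged over loci) and SFS (the site
frequency spectrum in 8 bins, folded unless an outgroup is declared).
Custom models, priors and statistic sets are registrable at run time
through the same registries.
"""

from __future__ import annotations

import heapq
import io
import itertools
import logging
import math
import os
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import coalsim, diversity
from .coalsim import (
    Bottleneck,
    DemographicModel,
    GrowthChange,
    MigrationChange,
    MutatorSpec,
    PopulationMerge,
    simulate_sfs_batch,
)
from .seqdata import Alignment

__all__ = [
    "Prior",
    "SampleConfig",
    "AbcModel",
    "StatSet",
    "SdzStats",
    "SfsStats",
    "Posterior",
    "AbcError",
    "builtin_models",
    "double_domestication_model",
    "get_model",
    "register_model",
    "get_stat_set",
    "register_stat_set",
    "register_prior",
    "get_prior",
    "compute_stats",
    "abc_sample",
    "read_table_meta",
    "abc_fit",
    "posterior_predictive",
]

logger = logging.getLogger(__name__)

SENTINEL = math.nan  # undefined statistic in tables


class AbcError(ValueError):
    """Invalid ABC configuration or input."""


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class _PriorParam:
    name: str
    dist: str           # 'uniform' | 'loguniform'
    lo: float
    hi: float
    transform: str      # 'none' | 'log' | 'logit'


class Prior:
    """Independent per-parameter prior distributions.

    Each parameter is uniform or log-uniform on (lo, hi).  ``transform``
    controls the scale used by the local-linear regression adjustment:
    'log' for positive scale parameters (default for log-uniform), 'logit'
    for rates bounded in (lo, hi), 'none' otherwise.
    """

    def __init__(self) -> None:
        self.params: list[_PriorParam] = []

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def _add(self, name, dist, lo, hi, transform):
        if not lo < hi:
            raise AbcError(f"prior for {name!r}: need lo < hi, got ({lo}, {hi})")
        if name in self.names:
            raise AbcError(f"duplicate prior parameter {name!r}")
        if transform not in ("none", "log", "logit"):
            raise AbcError(f"unknown transform {transform!r}")
        self.params.append(_PriorParam(name, dist, lo, hi, transform))
        return self

    def add_uniform(self, name: str, lo: float, hi: float,
                    transform: str = "none") -> "Prior":
        return self._add(name, "uniform", lo, hi, transform)

    def add_loguniform(self, name: str, lo: float, hi: float,
                       transform: str = "log") -> "Prior":
        if lo <= 0:
            raise AbcError("log-uniform needs lo > 0")
        return self._add(name, "loguniform", lo, hi, transform)

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {k: v for k, v in zip(self.names, self.draw_batch(rng, 1)[0])}

    def draw_batch(self, rng: np.random.Generator, m: int) -> np.ndarray:
        """m draws as an (m, nparams) array, column order = ``names``."""
        cols = []
        for p in self.params:
            u = rng.uniform(size=m)
            if p.dist == "uniform":
                cols.append(p.lo + u * (p.hi - p.lo))
            else:
                cols.append(np.exp(np.log(p.lo) + u * (np.log(p.hi) - np.log(p.lo))))
        return np.stack(cols, axis=1)

    def transform_of(self, name: str) -> _PriorParam:
        for p in self.params:
            if p.name == name:
                return p
        raise AbcError(f"unknown parameter {name!r}")


# ---------------------------------------------------------------------------
# Sample configuration
# ---------------------------------------------------------------------------

@dataclass
class SampleConfig:
    """What was sampled: gene copies per population, loci, outgroup."""

    samples: Sequence[int]
    nloci: int = 1
    outgroup: bool = False

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if not self.samples or any(s < 0 for s in self.samples):
            raise AbcError("samples must be non-negative counts per population")
        if self.nloci < 1:
            raise AbcError("nloci must be >= 1")

    @property
    def npop(self) -> int:
        return len(self.samples)

    @property
    def n(self) -> int:
        return sum(self.samples)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class AbcModel:
    """Plugin protocol for demographic models.

    Subclasses define ``name``, ``parameter_names`` and
    :meth:`demography`, which maps a sample configuration plus one
    parameter dict to a (DemographicModel, MutatorSpec) pair.  The
    constructor accepts a recombination flag; when set, a trailing ``rho``
    parameter is exposed and passed to the simulator.
    """

    name: str = "base"
    base_parameter_names: list[str] = []
    npop_required: int = 1

    def __init__(self, recomb: bool = False) -> None:
        self.recomb = recomb

    @property
    def parameter_names(self) -> list[str]:
        names = list(self.base_parameter_names)
        if self.recomb and "rho" not in names:
            names.append("rho")
        return names

    def validate_config(self, config: SampleConfig) -> None:
        if config.npop != self.npop_required:
            raise AbcError(
                f"model {self.name} needs {self.npop_required} population(s), "
                f"sample configuration has {config.npop}"
            )

    def demography(
        self, config: SampleConfig, params: dict[str, float]
    ) -> tuple[DemographicModel, MutatorSpec]:
        raise NotImplementedError

    def generate(
        self,
        config: SampleConfig,
        params: dict[str, float],
        rng: np.random.Generator,
    ) -> list[Alignment]:
        """Simulate ``config.nloci`` independent loci under *params*."""
        self.validate_config(config)
        model, mut = self.demography(config, params)
        return coalsim.coalesce(model, mut, config.nloci, rng,
                                outgroup=config.outgroup)

    # subclasses may provide generate_sfs(config, thetas, rng) -> xi array
    # for the vectorised bulk-simulation path
    supports_sfs_batch: bool = False


class SNM(AbcModel):
    """Standard neutral model: one constant-size panmictic population."""

    name = "SNM"
    base_parameter_names = ["theta"]

    def demography(self, config, params):
        model = DemographicModel(
            samples=config.samples,
            recomb_rate=params.get("rho", 0.0),
        )
        mut = MutatorSpec(kind="infinite_site", theta=params["theta"])
        return model, mut

    @property
    def supports_sfs_batch(self) -> bool:
        return not self.recomb

    def generate_sfs(self, config: SampleConfig, thetas: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
        """Batch of unfolded SFS, shape (len(thetas), nloci, n-1)."""
        n = config.n
        R = len(thetas)
        rep = np.repeat(np.asarray(thetas, float), config.nloci)
        xi = simulate_sfs_batch(n, rep, rng)
        return xi.reshape(R, config.nloci, n - 1)


class SNMR(SNM):
    """Standard neutral model with intra-locus recombination."""

    name = "SNMR"

    def __init__(self, recomb: bool = True) -> None:
        super().__init__(recomb=True)


class PEMR(AbcModel):
    """Exponentially growing population with recombination.

    ``growth`` is the scaled exponential growth rate (backward in time the
    size shrinks as exp(-growth * t)).
    """

    name = "PEMR"
    base_parameter_names = ["theta", "growth", "rho"]

    def __init__(self, recomb: bool = True) -> None:
        super().__init__(recomb=False)  # rho is already a base parameter

    def demography(self, config, params):
        model = DemographicModel(
            samples=config.samples,
            recomb_rate=params["rho"],
            events=[GrowthChange(time=0.0, alpha=params["growth"])],
        )
        return model, MutatorSpec(kind="infinite_site", theta=params["theta"])


class BNM(AbcModel):
    """Bottleneck model: instantaneous bottleneck of a given strength
    (extra coalescent time) at a given date."""

    name = "BNM"
    base_parameter_names = ["theta", "date", "strength"]

    def demography(self, config, params):
        if params["date"] <= 0:
            raise AbcError("bottleneck date must be > 0")
        model = DemographicModel(
            samples=config.samples,
            recomb_rate=params.get("rho", 0.0),
            events=[Bottleneck(time=params["date"], pop=0,
                               strength=params["strength"])],
        )
        return model, MutatorSpec(kind="infinite_site", theta=params["theta"])


class IM(AbcModel):
    """Isolation with migration: two populations that split at ``date``
    (backward: merge), with relative size ``size2`` for the second and
    symmetric migration ``migr`` since the split."""

    name = "IM"
    base_parameter_names = ["theta", "date", "size2", "migr"]
    npop_required = 2

    def demography(self, config, params):
        if params["date"] <= 0 or params["size2"] <= 0:
            raise AbcError("IM needs date > 0 and size2 > 0")
        model = DemographicModel(
            samples=config.samples,
            sizes=[1.0, params["size2"]],
            migration=params["migr"],
            recomb_rate=params.get("rho", 0.0),
            events=[PopulationMerge(time=params["date"], source=1, dest=0)],
        )
        return model, MutatorSpec(kind="infinite_site", theta=params["theta"])


class AM(AbcModel):
    """Ancient migration: two populations split at ``date``; migration at
    rate ``migr`` operated only in the older half of the divergence
    (backward: switched on at ``date / 2``, off at present)."""

    name = "AM"
    base_parameter_names = ["theta", "date", "migr"]
    npop_required = 2

    def demography(self, config, params):
        if params["date"] <= 0:
            raise AbcError("AM needs date > 0")
        model = DemographicModel(
            samples=config.samples,
            migration=0.0,
            recomb_rate=params.get("rho", 0.0),
            events=[
                MigrationChange(time=params["date"] / 2.0, rate=params["migr"]),
                PopulationMerge(time=params["date"], source=1, dest=0),
            ],
        )
        return model, MutatorSpec(kind="infinite_site", theta=params["theta"])


class DoubleDomestication(AbcModel):
    """Worked example of the user-model protocol: double, simultaneous
    domestication from two partially isolated wild stocks.

    Populations are ordered (wild1, wild2, cult1, cult2).  The wild pair
    exchanges migrants at rate ``migr1`` throughout; each cultivated
    population, of relative size ``size``, was founded from its wild source
    at time ``date`` (implemented backward as merges cult1 -> wild1 and
    cult2 -> wild2) and the cultivated pair exchanges at ``migr2`` since
    then.  ``migr1`` must be positive for the wild stocks to share
    ancestry.
    """

    name = "DOM2"
    base_parameter_names = ["theta", "date", "size", "migr1", "migr2"]
    npop_required = 4

    def demography(self, config, params):
        if params["date"] <= 0:
            raise AbcError("domestication date must be > 0")
        if params["size"] <= 0:
            raise AbcError("cultivated population size must be > 0")
        m1, m2 = params["migr1"], params["migr2"]
        if m1 <= 0:
            raise AbcError("migr1 must be > 0 (wild stocks must communicate)")
        mig = np.zeros((4, 4))
        mig[0, 1] = mig[1, 0] = m1
        mig[2, 3] = mig[3, 2] = m2
        model = DemographicModel(
            samples=config.samples,
            sizes=[1.0, 1.0, params["size"], params["size"]],
            migration=mig,
            recomb_rate=params.get("rho", 0.0),
            events=[
                PopulationMerge(time=params["date"], source=2, dest=0),
                PopulationMerge(time=params["date"], source=3, dest=1),
            ],
        )
        return model, MutatorSpec(kind="infinite_site", theta=params["theta"])


def double_domestication_model(recomb: bool = False) -> DoubleDomestication:
    """The double-domestication example model (see class docstring)."""
    return DoubleDomestication(recomb=recomb)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

class StatSet:
    """Plugin protocol for summary-statistic sets.

    ``names(config)`` gives the fixed output layout for a sampling
    configuration; ``compute(alignments, config)`` returns the matching
    vector (NaN marks an undefined statistic).  Sets that can be computed
    directly from an unfolded SFS additionally provide ``from_sfs``.
    """

    name: str = "base"

    def names(self, config: SampleConfig) -> list[str]:
        raise NotImplementedError

    def compute(self, alignments: Sequence[Alignment],
                config: SampleConfig) -> np.ndarray:
        raise NotImplementedError

    supports_sfs: bool = False


def _sfs_stats_from_xi(xi: np.ndarray, n: int):
    """Vectorised (S, pi, thetaH) from unfolded SFS counts (R, n-1)."""
    d = np.arange(1, n)
    S = xi.sum(axis=1)
    pi = xi @ (2.0 * d * (n - d)) / (n * (n - 1.0))
    thetaH = xi @ (2.0 * d**2) / (n * (n - 1.0))
    return S, pi, thetaH


def _tajima_d_vec(S: np.ndarray, pi: np.ndarray, n: int) -> np.ndarray:
    c = diversity.tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = (pi - S / c["a1"]) / np.sqrt(var)
    return np.where((S > 0) & (var > 0), D, np.nan)


class SdzStats(StatSet):
    """(S, Tajima's D, Fay & Wu's H), each averaged across loci.

    Without an outgroup H cannot be polarised and the set degrades to
    (S, D) with a logged warning.  Per-locus D (and H) are NaN when S = 0;
    loci with undefined values are excluded from the average.
    """

    name = "SDZ"

    def names(self, config: SampleConfig) -> list[str]:
        if config.outgroup:
            return ["S", "D", "H"]
        logger.warning("SDZ without outgroup: H unavailable, using (S, D)")
        return ["S", "D"]

    def compute(self, alignments, config):
        S_l, D_l, H_l = [], [], []
        for aln in alignments:
            st = diversity.nucleotide_stats(aln)
            S_l.append(st.S)
            D_l.append(st.D)
            H_l.append(st.H)
        out = [float(np.mean(S_l)), _nanmean(D_l)]
        if config.outgroup:
            out.append(_nanmean(H_l))
        return np.array(out)

    supports_sfs = True

    def from_sfs(self, xi: np.ndarray, config: SampleConfig) -> np.ndarray:
        """(R, nloci, n-1) SFS batch -> (R, nstats) per-replicate vectors."""
        R, nloci, _ = xi.shape
        n = config.n
        flat = xi.reshape(R * nloci, n - 1)
        S, pi, thetaH = _sfs_stats_from_xi(flat, n)
        D = _tajima_d_vec(S, pi, n)
        H = np.where(S > 0, pi - thetaH, np.nan)
        S = S.reshape(R, nloci)
        D = D.reshape(R, nloci)
        H = H.reshape(R, nloci)
        cols = [S.mean(axis=1), _nanmean_rows(D)]
        if config.outgroup:
            cols.append(_nanmean_rows(H))
        return np.stack(cols, axis=1)


def _nanmean(values) -> float:
    arr = np.asarray(values, dtype=float)
    good = ~np.isnan(arr)
    return float(arr[good].mean()) if good.any() else math.nan


def _nanmean_rows(arr: np.ndarray) -> np.ndarray:
    good = ~np.isnan(arr)
    cnt = good.sum(axis=1)
    tot = np.where(good, arr, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)


N_SFS_BINS = 8


class SfsStats(StatSet):
    """Site frequency spectrum in 8 equal-width bins, pooled across loci.

    Unfolded (derived-allele frequency in (0, 1)) when an outgroup is
    declared, folded (minor-allele frequency in (0, 1/2]) otherwise.
    Normalised to sum to 1 when S > 0; the all-zero vector otherwise.
    """

    name = "SFS"

    def names(self, config: SampleConfig) -> list[str]:
        return [f"sfs{i + 1}" for i in range(N_SFS_BINS)]

    @staticmethod
    def _bin(freqs: np.ndarray, folded: bool) -> np.ndarray:
        top = 0.5 if folded else 1.0
        edges = np.linspace(0.0, top, N_SFS_BINS + 1)
        idx = np.clip(np.searchsorted(edges, freqs, side="left") - 1,
                      0, N_SFS_BINS - 1)
        hist = np.bincount(idx, minlength=N_SFS_BINS).astype(float)
        total = hist.sum()
        return hist / total if total > 0 else hist

    def compute(self, alignments, config):
        freqs = []
        folded = not config.outgroup
        for aln in alignments:
            for sv in diversity.survey_sites(aln):
                if not sv.is_polymorphic:
                    continue
                ne = sv.n_effective
                if folded:
                    minor = min(sv.allele_counts.values())
                    freqs.append(minor / ne)
                else:
                    anc = sv.outgroup_allele
                    if anc is None or anc not in sv.allele_counts:
                        continue
                    for allele, cnt in sv.allele_counts.items():
                        if allele != anc:
                            freqs.append(cnt / ne)
        if not freqs:
            return np.zeros(N_SFS_BINS)
        return self._bin(np.array(freqs), folded)

    supports_sfs = True

    def from_sfs(self, xi: np.ndarray, config: SampleConfig) -> np.ndarray:
        R, nloci, nm1 = xi.shape
        n = config.n
        d = np.arange(1, n)
        folded = not config.outgroup
        counts = xi.sum(axis=1)  # pooled across loci: (R, n-1)
        freqs = (np.minimum(d, n - d) if folded else d) / n
        top = 0.5 if folded else 1.0
        edges = np.linspace(0.0, top, N_SFS_BINS + 1)
        idx = np.clip(np.searchsorted(edges, freqs, side="left") - 1,
                      0, N_SFS_BINS - 1)
        out = np.zeros((R, N_SFS_BINS))
        for b in range(N_SFS_BINS):
            out[:, b] = counts[:, idx == b].sum(axis=1)
        tot = out.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            out = np.where(tot > 0, out / tot, 0.0)
        return out


def compute_stats(stat_set: StatSet, alignments: Sequence[Alignment],
                  config: SampleConfig) -> dict[str, float]:
    """Summary statistics of a set of alignments as a named vector."""
    if not alignments:
        raise AbcError("no alignments to summarise")
    values = stat_set.compute(alignments, config)
    return dict(zip(stat_set.names(config), values.tolist()))


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

_MODEL_REGISTRY: dict[str, Callable[..., AbcModel]] = {}
_STAT_REGISTRY: dict[str, Callable[[], StatSet]] = {}
_PRIOR_REGISTRY: dict[str, Prior] = {}


def register_model(factory: Callable[..., AbcModel],
                   name: str | None = None) -> None:
    """Add a model class/factory to the run-time registry."""
    probe = factory()
    _MODEL_REGISTRY[name or probe.name] = factory


def get_model(name: str, recomb: bool = False) -> AbcModel:
    if name not in _MODEL_REGISTRY:
        raise AbcError(
            f"unknown model {name!r}; registered models: "
            f"{', '.join(sorted(_MODEL_REGISTRY))}"
        )
    return _MODEL_REGISTRY[name](recomb=recomb)


def list_models() -> list[str]:
    return sorted(_MODEL_REGISTRY)


def builtin_models() -> dict[str, AbcModel]:
    """The six pre-defined demographic models, by name."""
    return {cls.name: cls() for cls in (SNM, SNMR, PEMR, BNM, IM, AM)}


def register_stat_set(factory: Callable[[], StatSet],
                      name: str | None = None) -> None:
    probe = factory()
    _STAT_REGISTRY[name or probe.name] = factory


def get_stat_set(name: str) -> StatSet:
    if name not in _STAT_REGISTRY:
        raise AbcError(
            f"unknown stat set {name!r}; registered: "
            f"{', '.join(sorted(_STAT_REGISTRY))}"
        )
    return _STAT_REGISTRY[name]()


def register_prior(name: str, prior: Prior) -> None:
    _PRIOR_REGISTRY[name] = prior


def get_prior(name: str) -> Prior:
    if name not in _PRIOR_REGISTRY:
        raise AbcError(
            f"unknown prior {name!r}; registered: "
            f"{', '.join(sorted(_PRIOR_REGISTRY))}"
        )
    return _PRIOR_REGISTRY[name]


for _cls in (SNM, SNMR, PEMR, BNM, IM, AM, DoubleDomestication):
    register_model(_cls)
register_stat_set(SdzStats)
register_stat_set(SfsStats)


# ---------------------------------------------------------------------------
# Sampling (table production)
# ---------------------------------------------------------------------------

_BATCH = 5000


def abc_sample(
    model: AbcModel,
    prior: Prior,
    stat_set: StatSet,
    nsims: int,
    config: SampleConfig,
    seed: int,
    sink: str | os.PathLike,
    resume: bool = False,
) -> int:
    """Simulate *nsims* prior draws and stream the ABC table to *sink*.

    The table is TSV: a ``# model=... nsims=... seed=...`` metadata line, a
    header of parameter then statistic names, then one row per simulation.
    Rows are written as they are produced; nothing is accumulated in
    memory.  With ``resume=True`` an existing table is extended up to
    *nsims* total rows.  Returns the number of rows written in this call.

    When the model and statistic set both support it (single-population
    neutral models with SFS-derived statistics), simulation runs through a
    vectorised batch kernel; otherwise each replicate runs through the
    generic ancestral-recombination-graph simulator.
    """
    if nsims < 1:
        raise AbcError("nsims must be >= 1")
    model.validate_config(config)
    stat_names = stat_set.names(config)
    param_names = model.parameter_names
    if set(param_names) - set(prior.names):
        raise AbcError(
            f"prior does not cover model parameters: "
            f"missing {sorted(set(param_names) - set(prior.names))}"
        )
    start = 0
    mode = "w"
    if resume and os.path.exists(sink):
        with open(sink) as fh:
            start = max(0, sum(1 for _ in fh) - 2)
        mode = "a"
    fast = (getattr(model, "supports_sfs_batch", False)
            and getattr(stat_set, "supports_sfs", False)
            and not model.recomb)
    written = 0
    with open(sink, mode) as fh:
        if start == 0 and mode == "w":
            fh.write(f"# model={model.name} nsims={nsims} seed={seed}\n")
            fh.write("\t".join(list(prior.names) + stat_names) + "\n")
        row = start
        while row < nsims:
            m = min(_BATCH, nsims - row)
            rng = np.random.default_rng([seed, row])
            draws = prior.draw_batch(rng, m)
            if fast:
                thetas = draws[:, prior.names.index("theta")]
                xi = model.generate_sfs(config, thetas, rng)
                stats = stat_set.from_sfs(xi, config)
                block = np.concatenate([draws, stats], axis=1)
                np.savetxt(fh, block, delimiter="\t", fmt="%.17g")
            else:
                for i in range(m):
                    params = dict(zip(prior.names, draws[i]))
                    alns = model.generate(config, params, rng)
                    vec = stat_set.compute(alns, config)
                    vals = list(draws[i]) + list(vec)
                    fh.write("\t".join(format(v, ".17g") for v in vals) + "\n")
            written += m
            row += m
    return written


def read_table_meta(path: str | os.PathLike) -> dict:
    """Metadata line + header of an ABC table."""
    with open(path) as fh:
        meta_line = fh.readline().strip()
        header = fh.readline().strip().split("\t")
    meta = {}
    if meta_line.startswith("#"):
        for tok in meta_line[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    return {"meta": meta, "columns": header}


def _iter_chunks(path, chunksize):
    """Stream a table as DataFrames of at most *chunksize* rows.

    Reads line batches and parses them with numpy, so peak memory is set
    by the chunk size, not the file size.
    """
    with open(path) as fh:
        fh.readline()  # metadata line
        header = fh.readline().strip().split("\t")
        while True:
            lines = list(itertools.islice(fh, chunksize))
            if not lines:
                return
            arr = np.loadtxt(io.StringIO("".join(lines)),
                             delimiter="\t", ndmin=2)
            yield pd.DataFrame(arr, columns=header)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _transforms_for(param_names, prior: Prior | None):
    """Per-parameter (forward, inverse) transform pairs for regression."""
    out = []
    for name in param_names:
        kind = "none"
        lo = hi = None
        if prior is not None and name in prior.names:
            p = prior.transform_of(name)
            kind, lo, hi = p.transform, p.lo, p.hi
        if kind == "log":
            out.append((np.log, np.exp))
        elif kind == "logit":
            span = hi - lo

            def fwd(x, lo=lo, span=span):
                z = np.clip((x - lo) / span, 1e-12, 1 - 1e-12)
                return np.log(z / (1 - z))

            def inv(y, lo=lo, span=span):
                return lo + span / (1.0 + np.exp(-y))

            out.append((fwd, inv))
        else:
            out.append((lambda x: x, lambda x: x))
    return out


@dataclass
class Posterior:
    """Accepted (and optionally regression-adjusted) parameter sample.

    ``accepted`` holds the raw accepted draws, ``adjusted`` the
    local-linear-regression corrected values (equal to ``accepted`` under
    plain rejection), both as DataFrames over the parameter columns;
    ``weights`` are the kernel weights used in the regression (all 1 under
    rejection) and ``distances`` the standardised distances to the
    observed vector.
    """

    accepted: pd.DataFrame
    adjusted: pd.DataFrame
    weights: np.ndarray
    distances: np.ndarray
    tolerance: float
    method: str

    def __len__(self) -> int:
        return len(self.accepted)

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        """Weighted quantiles of the adjusted sample, one row per q."""
        rows = {}
        for col in self.adjusted.columns:
            rows[col] = [
                _weighted_quantile(self.adjusted[col].to_numpy(),
                                   self.weights, q)
                for q in qs
            ]
        return pd.DataFrame(rows, index=[f"q{q}" for q in qs])

    def mode(self, bins: int = 30) -> dict[str, float]:
        """Marginal posterior mode via a weighted histogram."""
        out = {}
        for col in self.adjusted.columns:
            x = self.adjusted[col].to_numpy()
            hist, edges = np.histogram(x, bins=bins, weights=self.weights)
            b = int(np.argmax(hist))
            out[col] = 0.5 * (edges[b] + edges[b + 1])
        return out

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# posterior tolerance={self.tolerance} "
                     f"method={self.method}\n")
            cols = list(self.adjusted.columns)
            header = (cols + [c + "_raw" for c in cols]
                      + ["weight", "distance"])
            fh.write("\t".join(header) + "\n")
            block = np.concatenate(
                [self.adjusted.to_numpy(), self.accepted.to_numpy(),
                 self.weights[:, None], self.distances[:, None]], axis=1)
            np.savetxt(fh, block, delimiter="\t", fmt="%.17g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "Posterior":
        with open(path) as fh:
            meta_line = fh.readline().strip()
            df = pd.read_csv(fh, sep="\t")
        tol = 1.0
        method = "rejection"
        for tok in meta_line.lstrip("#").split():
            if tok.startswith("tolerance="):
                tol = float(tok.split("=")[1])
            elif tok.startswith("method="):
                method = tok.split("=")[1]
        cols = [c for c in df.columns
                if not c.endswith("_raw") and c not in ("weight", "distance")]
        return cls(
            accepted=df[[c + "_raw" for c in cols]].rename(
                columns=lambda c: c[:-4]),
            adjusted=df[cols].copy(),
            weights=df["weight"].to_numpy(),
            distances=df["distance"].to_numpy(),
            tolerance=tol,
            method=method,
        )


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    x, w = x[order], np.asarray(w, float)[order]
    if w.sum() <= 0:
        w = np.ones_like(w)
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(q, cw, x))


def abc_fit(
    table: str | os.PathLike,
    observed: dict[str, float],
    tolerance: float,
    adjust: str = "loclinear",
    prior: Prior | None = None,
    chunksize: int = 20_000,
) -> Posterior:
    """Rejection (+ optional local-linear regression) fit of an ABC table.

    The table is streamed twice: pass one estimates each used statistic's
    standard deviation; pass two computes standardised Euclidean distances
    to *observed* and keeps the closest ``ceil(tolerance * N)`` valid rows
    (rows with an undefined value in a used statistic are excluded, with a
    logged count; ties at the acceptance boundary are broken by row order).
    ``adjust='loclinear'`` then regresses parameters on statistics over the
    accepted rows with Epanechnikov weights and shifts each draw to the
    observed point (on transformed scales for bounded parameters, as
    declared by *prior*); it falls back to plain rejection when the
    accepted set is smaller than the statistic count + 1 or the design is
    singular.
    """
    if not 0 < tolerance <= 1:
        raise AbcError("tolerance must be in (0, 1]")
    if adjust not in ("rejection", "loclinear"):
        raise AbcError("adjust must be 'rejection' or 'loclinear'")
    info = read_table_meta(table)
    columns = info["columns"]
    stat_names = [c for c in columns if c in observed]
    missing = set(observed) - set(columns)
    if missing:
        raise AbcError(f"observed statistics not in table: {sorted(missing)}")
    if not stat_names:
        raise AbcError("no observed statistic matches the table header")
    param_names = [c for c in columns if c not in observed]

    # pass 1: count + scale
    n_valid = 0
    n_dropped = 0
    s = np.zeros(len(stat_names))
    s2 = np.zeros(len(stat_names))
    for chunk in _iter_chunks(table, chunksize):
        block = chunk[stat_names].to_numpy()
        ok = ~np.isnan(block).any(axis=1)
        n_dropped += int((~ok).sum())
        block = block[ok]
        n_valid += block.shape[0]
        s += block.sum(axis=0)
        s2 += (block**2).sum(axis=0)
    if n_dropped:
        logger.warning("%d rows with undefined statistics excluded", n_dropped)
    if n_valid == 0:
        raise AbcError("no valid rows in the table")
    mean = s / n_valid
    var = np.maximum(s2 / n_valid - mean**2, 0.0)
    sd = np.sqrt(var)
    usable = sd > 0
    if not usable.all():
        dropped = [nm for nm, u in zip(stat_names, usable) if not u]
        logger.warning("zero-variance statistic(s) dropped: %s", dropped)
    use_names = [nm for nm, u in zip(stat_names, usable) if u]
    if not use_names:
        raise AbcError("all statistics have zero variance")
    sd_use = sd[usable]
    obs_vec = np.array([observed[nm] for nm in use_names]) / sd_use

    m_accept = math.ceil(tolerance * n_valid)

    # pass 2: distances + selection (bounded memory: heap of size m_accept)
    heap: list[tuple[float, int, tuple, tuple]] = []  # (-d, -row, params, stats)
    row_base = 0
    for chunk in _iter_chunks(table, chunksize):
        stats_all = chunk[stat_names].to_numpy()
        ok = ~np.isnan(stats_all).any(axis=1)
        stats_use = chunk[use_names].to_numpy()[ok] / sd_use
        params = chunk[param_names].to_numpy()[ok]
        d = np.sqrt(((stats_use - obs_vec) ** 2).sum(axis=1))
        rows = row_base + np.flatnonzero(ok)
        for k in range(d.shape[0]):
            item = (-d[k], -int(rows[k]), tuple(params[k]),
                    tuple(stats_use[k]))
            if len(heap) < m_accept:
                heapq.heappush(heap, item)
            elif item > heap[0]:
                heapq.heapreplace(heap, item)
        row_base += len(chunk)

    heap.sort(reverse=True)  # ascending distance, then row order
    dists = np.array([-h[0] for h in heap])
    acc_params = np.array([h[2] for h in heap])
    acc_stats = np.array([h[3] for h in heap])
    accepted = pd.DataFrame(acc_params, columns=param_names)

    if adjust == "rejection":
        return Posterior(
            accepted=accepted, adjusted=accepted.copy(),
            weights=np.ones(len(accepted)), distances=dists,
            tolerance=tolerance, method="rejection",
        )

    # local-linear regression adjustment (Epanechnikov kernel)
    d_max = dists.max()
    if d_max == 0:
        weights = np.ones(len(dists))
    else:
        weights = 1.0 - (dists / d_max) ** 2
    X = np.column_stack([np.ones(len(acc_stats)),
                         acc_stats - obs_vec[None, :]])
    nstat = len(use_names)
    if len(accepted) < nstat + 2:
        logger.warning("accepted set too small for regression; "
                       "falling back to rejection")
        return Posterior(accepted=accepted, adjusted=accepted.copy(),
                         weights=np.ones(len(accepted)), distances=dists,
                         tolerance=tolerance, method="rejection")
    W = weights
    XtW = X.T * W
    gram = XtW @ X
    transforms = _transforms_for(param_names, prior)
    adjusted = {}
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        logger.warning("singular regression design; falling back to rejection")
        return Posterior(accepted=accepted, adjusted=accepted.copy(),
                         weights=np.ones(len(accepted)), distances=dists,
                         tolerance=tolerance, method="rejection")
    for j, name in enumerate(param_names):
        fwd, inv = transforms[j]
        y = fwd(acc_params[:, j])
        beta = gram_inv @ (XtW @ y)
        resid_shift = (X[:, 1:] @ beta[1:])
        adjusted[name] = inv(y - resid_shift)
    return Posterior(
        accepted=accepted,
        adjusted=pd.DataFrame(adjusted, columns=param_names),
        weights=weights,
        distances=dists,
        tolerance=tolerance,
        method="loclinear",
    )


# ---------------------------------------------------------------------------
# Posterior utilities
# ---------------------------------------------------------------------------

def posterior_predictive(
    post: Posterior,
    model: AbcModel,
    stat_set: StatSet,
    config: SampleConfig,
    nsim: int,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Re-simulate under parameters drawn from the posterior.

    Draws *nsim* parameter vectors from the adjusted posterior (with its
    weights) and returns the simulated summary-statistic vectors, one row
    per draw — the null distribution for posterior predictive checks.
    """
    if len(post) == 0:
        raise AbcError("empty posterior")
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    w = post.weights.copy()
    if w.sum() <= 0:
        w = np.ones(len(post))
    idx = rng.choice(len(post), size=nsim, p=w / w.sum())
    stat_names = stat_set.names(config)
    rows = []
    for i in idx:
        params = post.adjusted.iloc[int(i)].to_dict()
        alns = model.generate(config, params, rng)
        rows.append(stat_set.compute(alns, config))
    return pd.DataFrame(np.array(rows), columns=stat_names)
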