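"""Synthetic multi-locus eDNA count generator with planted structure.

Produces per-locus OTU count tables (field samples with PCR replicates
plus negative/blank controls), a sample metadata table, a taxonomy
table, environmental covariates statistically linked to planted
community modules, and a ground-truth record for parameter-recovery
testing.

The generative model, top to bottom:

1.  Taxa are partitioned into modules; each module has a unimodal
    seasonal archetype (an asymmetric bump on the time cycle peaking at
    a module-specific time point).  Taxon latent abundance is the
    module archetype perturbed by log-normal noise; values below a
    configurable floor become exact zero so genuine absences can exist.
2.  Environmental variables are affine transforms of selected module
    archetypes plus noise; at least one variable is pure noise.
3.  Reads per locus and PCR replicate follow a multinomial whose
    propensities are latent abundance times a fixed per-taxon-per-locus
    amplification efficiency (log-normal with a zero-mass spike) times
    a per-replicate Bernoulli detection indicator, mixed with a
    contaminant pool.  Controls draw from the contaminant pool only.
    Terrestrial taxa are injected exclusively as contaminants.

All randomness flows through :func:`numpy.random.default_rng` streams
derived from ``scenario.seed``; identical scenarios give bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

ENV_VARIABLES = ("temperature", "salinity", "dissolved_oxygen", "chlorophyll_a", "nitrate")

#: baseline level and dynamic amplitude used when synthesising each variable
_ENV_PARAMS = {
    "temperature": (12.0, 6.0),
    "salinity": (33.5, 1.5),
    "dissolved_oxygen": (6.0, 2.0),
    "chlorophyll_a": (2.0, 3.0),
    "nitrate": (8.0, 5.0),
}

_LOCUS_NAMES = ("16S", "18S", "COI", "12S", "ITS", "rbcL", "matK", "trnL")


@dataclass(frozen=True)
class CommunityScenario:
    """Parameters of one synthetic community experiment.

    Counts must be >= 1, probabilities in [0, 1], and
    ``terrestrial_fraction`` in [0, 1).
    """

    n_taxa: int = 120
    n_modules: int = 6
    n_timepoints: int = 8
    n_loci: int = 4
    n_replicates: int = 3
    library_size: int = 20000
    detection_prob: float = 0.95
    contamination_rate: float = 0.03
    n_controls: int = 4
    terrestrial_fraction: float = 0.1
    seed: int = 0
    sigma: float = 0.3
    archetype_rise: float = 0.5
    archetype_fall: float = 2.0
    abundance_floor: float = 0.05
    zero_efficiency_fraction: float = 0.25
    control_depth_factor: float = 0.05
    fixed_depth: bool = True
    plant_hubs: bool = True
    n_linked_env: int = 3
    env_noise: float = 0.2
    otus_per_taxon: int = 1
    corrupt_timepoint: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_taxa", "n_modules", "n_timepoints", "n_loci",
                     "n_replicates", "library_size", "otus_per_taxon"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("detection_prob", "contamination_rate",
                     "zero_efficiency_fraction", "control_depth_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.terrestrial_fraction < 1.0:
            raise ValueError("terrestrial_fraction must be in [0, 1)")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        if self.n_community_taxa < self.n_modules:
            raise ValueError("not enough non-terrestrial taxa to fill the modules")
        if self.corrupt_timepoint is not None and not (
                0 <= self.corrupt_timepoint < self.n_timepoints):
            raise ValueError("corrupt_timepoint outside the time axis")

    @property
    def n_terrestrial(self) -> int:
        return int(round(self.terrestrial_fraction * self.n_taxa))

    @property
    def n_community_taxa(self) -> int:
        return self.n_taxa - self.n_terrestrial

    @property
    def loci(self) -> tuple[str, ...]:
        if self.n_loci <= len(_LOCUS_NAMES):
            return _LOCUS_NAMES[: self.n_loci]
        extra = tuple(f"locus{i}" for i in range(len(_LOCUS_NAMES), self.n_loci))
        return _LOCUS_NAMES + extra

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CommunityScenario":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**dict(data))


@dataclass
class LatentAbundance:
    """True (unobserved) organismal abundance and its planted structure."""

    abundance: pd.DataFrame          # taxa x timepoints, nonnegative
    module_truth: dict[str, str]     # taxon -> module label
    archetypes: pd.DataFrame         # module x timepoints seasonal profiles
    peaks: dict[str, int]            # module -> archetype peak time index
    hubs: dict[str, str]             # module -> planted noise-free hub taxon


@dataclass
class GeneratorOutput:
    """Everything a downstream pipeline consumes, plus the truth."""

    counts: dict[str, pd.DataFrame]  # locus -> OTUs x samples integer counts
    metadata: pd.DataFrame           # sample_id, sample_type, timepoint, replicate
    taxonomy: pd.DataFrame           # per-OTU rank labels, habitat, trophic level
    environment: pd.DataFrame        # timepoints x variables
    truth: dict


def _stream(scenario: CommunityScenario, stage: int) -> np.random.Generator:
    """Independent deterministic RNG stream per generation stage."""
    return np.random.default_rng(np.random.SeedSequence([int(scenario.seed), stage]))


def _archetype_peaks(n_modules: int, n_timepoints: int) -> np.ndarray:
    """Evenly spaced (possibly fractional) bump centres on the seasonal cycle.

    Centres are fractional so inter-module separation is uniform; the
    on-grid argmax of every archetype is still a distinct time point.
    """
    if n_modules > n_timepoints:
        raise ValueError(
            f"cannot place {n_modules} distinct archetype peaks on "
            f"{n_timepoints} time points")
    return np.linspace(0, n_timepoints, n_modules, endpoint=False)


def generate_latent_dynamics(
    scenario: CommunityScenario,
    rng: np.random.Generator | None = None,
) -> LatentAbundance:
    """Plant module-structured latent abundance trajectories.

    Taxon ``i`` in module ``g`` has abundance
    ``A_i(t) = exp(log s_g(t) + eps_it)`` with
    ``eps_it ~ Normal(0, sigma^2)``; archetypes ``s_g`` are unimodal
    seasonal bumps (rise rate ``archetype_rise``, decay rate
    ``archetype_fall`` in log units per time step) peaking at distinct
    time points.  Values below ``abundance_floor`` times the taxon's
    maximum are zeroed.
    """
    rng = _stream(scenario, 0) if rng is None else rng
    T, M = scenario.n_timepoints, scenario.n_modules
    peaks = _archetype_peaks(M, T)
    t_axis = np.arange(T, dtype=float)
    modules = [f"M{g + 1}" for g in range(M)]
    # asymmetric seasonal bump on the time cycle: a slow build-up toward
    # the peak and a fast post-peak decay.  The asymmetry keeps every
    # pair of module archetypes rank-distinguishable (a symmetric bump
    # makes opposite-season modules exact anti-correlates, which an
    # unsigned |tau|-based network cannot tell apart), and the modest
    # dynamic range keeps off-season taxa sequenceable.
    ahead = (t_axis[None, :] - peaks[:, None]) % T      # time since peak
    behind = (-(t_axis[None, :] - peaks[:, None])) % T  # time until peak
    arch = np.exp(-np.minimum(scenario.archetype_fall * ahead,
                              scenario.archetype_rise * behind))
    archetypes = pd.DataFrame(arch, index=modules, columns=range(T))

    n = scenario.n_community_taxa
    taxa = [f"taxon_{i:03d}" for i in range(n)]
    # contiguous, near-equal module blocks
    assignment = np.array_split(np.arange(n), M)
    module_of = np.empty(n, dtype=int)
    for g, idx in enumerate(assignment):
        module_of[idx] = g

    eps = rng.normal(0.0, scenario.sigma, size=(n, T))
    hubs: dict[str, str] = {}
    if scenario.plant_hubs:
        for g, idx in enumerate(assignment):
            eps[idx[0]] = 0.0
            hubs[modules[g]] = taxa[idx[0]]
    A = arch[module_of] * np.exp(eps)
    row_max = A.max(axis=1, keepdims=True)
    A[A < scenario.abundance_floor * row_max] = 0.0

    abundance = pd.DataFrame(A, index=taxa, columns=range(T))
    module_truth = {taxa[i]: modules[module_of[i]] for i in range(n)}
    peak_map = {modules[g]: int(np.argmax(arch[g])) for g in range(M)}
    return LatentAbundance(abundance, module_truth, archetypes, peak_map, hubs)


def generate_environment(
    scenario: CommunityScenario,
    latent: LatentAbundance,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthesise environmental covariates linked to module archetypes.

    Each linked variable ``v`` satisfies
    ``v(t) = alpha + amp * s_g(t) + Normal(0, tau^2)`` with
    ``tau = env_noise * amp * sd(s_g)``; the remaining variables are
    pure noise.  Returns the table and the variable -> module linkage
    map.
    """
    rng = _stream(scenario, 1) if rng is None else rng
    T = scenario.n_timepoints
    modules = list(latent.archetypes.index)
    n_linked = min(scenario.n_linked_env, len(modules), len(ENV_VARIABLES) - 1)
    links: dict[str, str] = {}
    env: dict[str, np.ndarray] = {}
    for j, var in enumerate(ENV_VARIABLES):
        alpha, amp = _ENV_PARAMS[var]
        if j < n_linked:
            module = modules[j]
            s = latent.archetypes.loc[module].to_numpy()
            tau = scenario.env_noise * abs(amp) * float(np.std(s))
            env[var] = alpha + amp * s + rng.normal(0.0, tau, size=T)
            links[var] = module
        else:
            env[var] = alpha + 0.5 * abs(amp) * rng.standard_normal(T)
    table = pd.DataFrame(env, index=range(T))
    table.index.name = "timepoint"
    return table, links


def _efficiency_matrix(
    scenario: CommunityScenario,
    n_rows: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Log-normal(0,1) per taxon-locus, with a zero-mass spike."""
    E = rng.lognormal(0.0, 1.0, size=(n_rows, scenario.n_loci))
    E[rng.random((n_rows, scenario.n_loci)) < scenario.zero_efficiency_fraction] = 0.0
    # every taxon must amplify at >=1 locus, or it is invisible by design
    dead = np.flatnonzero(E.sum(axis=1) == 0)
    for i in dead:
        E[i, rng.integers(scenario.n_loci)] = rng.lognormal(0.0, 1.0)
    return E


def generate_reads(
    scenario: CommunityScenario,
    latent: LatentAbundance,
    rng: np.random.Generator | None = None,
) -> GeneratorOutput:
    """Draw per-locus multinomial read tables plus metadata and truth.

    Field replicate propensities are
    ``w_il(t) = A_i(t) * E_il * Bernoulli(detection_prob)`` with the
    amplification efficiency ``E_il`` constant across samples; read
    vectors mix the normalized field propensities with the contaminant
    pool at ``contamination_rate``.  Controls draw from the contaminant
    pool only, at ``control_depth_factor`` of the library size.
    """
    rng = _stream(scenario, 2) if rng is None else rng
    env_table, env_links = generate_environment(scenario, latent)

    comm_taxa = list(latent.abundance.index)
    terr_taxa = [f"terr_{i:03d}" for i in range(scenario.n_terrestrial)]
    all_taxa = comm_taxa + terr_taxa
    n_comm, n_terr = len(comm_taxa), len(terr_taxa)

    E = _efficiency_matrix(scenario, len(all_taxa), rng)

    # fixed OTU split per taxon (constant across samples: acts as part of E)
    k = scenario.otus_per_taxon
    if k > 1:
        split = rng.dirichlet(np.ones(k), size=len(all_taxa))
        otus = [f"{t}_otu{j}" for t in all_taxa for j in range(k)]
    else:
        split = np.ones((len(all_taxa), 1))
        otus = list(all_taxa)
    otu_taxon_idx = np.repeat(np.arange(len(all_taxa)), k)
    otu_split = split.ravel()
    otu_to_taxon = {otus[i]: all_taxa[otu_taxon_idx[i]] for i in range(len(otus))}

    # taxonomy: rank label per taxon, shared by its OTUs
    rank_of_taxon = rng.choice(["family", "order", "class"], size=len(all_taxa),
                               p=[0.8, 0.15, 0.05])
    trophic_of_taxon = rng.integers(0, 6, size=len(all_taxa))
    tax_rows = []
    for i, otu in enumerate(otus):
        taxon = all_taxa[otu_taxon_idx[i]]
        rank = rank_of_taxon[otu_taxon_idx[i]]
        row = {"otu_id": otu, "family": "", "order": "", "class": "",
               "habitat": "terrestrial" if taxon in terr_taxa else "marine",
               "trophic_level": int(trophic_of_taxon[otu_taxon_idx[i]])}
        row[rank] = taxon
        tax_rows.append(row)
    taxonomy = pd.DataFrame(tax_rows).set_index("otu_id")

    # contaminant pool (terrestrial only); per-locus composition scaled by E
    if n_terr:
        pool_base = rng.dirichlet(np.ones(n_terr))
    else:
        pool_base = np.zeros(0)

    field_samples = [f"t{t}_r{r}" for t in range(scenario.n_timepoints)
                     for r in range(1, scenario.n_replicates + 1)]
    control_types = ["negative" if i % 2 == 0 else "blank"
                     for i in range(scenario.n_controls)]
    control_samples = [f"ctrl_{i}" for i in range(scenario.n_controls)]
    meta_rows = [
        {"sample_id": f"t{t}_r{r}", "sample_type": "field",
         "timepoint": t, "replicate": r}
        for t in range(scenario.n_timepoints)
        for r in range(1, scenario.n_replicates + 1)
    ] + [
        {"sample_id": sid, "sample_type": ctype, "timepoint": -1, "replicate": -1}
        for sid, ctype in zip(control_samples, control_types)
    ]
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    A = latent.abundance.to_numpy()
    counts: dict[str, pd.DataFrame] = {}
    c_rate = scenario.contamination_rate
    ctrl_depth = int(round(scenario.library_size * scenario.control_depth_factor))

    for li, locus in enumerate(scenario.loci):
        if n_terr:
            pool_w = pool_base * E[n_comm:, li]
            pool = pool_w / pool_w.sum() if pool_w.sum() > 0 else pool_w
        else:
            pool = np.zeros(0)
        pool_otu = np.zeros(len(otus))
        if n_terr:
            terr_rows = otu_taxon_idx >= n_comm
            pool_otu[terr_rows] = pool[otu_taxon_idx[terr_rows] - n_comm] \
                * otu_split[terr_rows]
            if pool_otu.sum() > 0:
                pool_otu /= pool_otu.sum()

        table = np.zeros((len(otus), len(field_samples) + len(control_samples)),
                         dtype=np.int64)
        col = 0
        for t in range(scenario.n_timepoints):
            for _r in range(scenario.n_replicates):
                detect = rng.random(n_comm) < scenario.detection_prob
                w_taxon = A[:, t] * E[:n_comm, li] * detect
                w_otu = w_taxon[otu_taxon_idx[otu_taxon_idx < n_comm]] \
                    * otu_split[otu_taxon_idx < n_comm]
                total = w_otu.sum()
                if total == 0:
                    col += 1  # all-zero column is a valid outcome
                    continue
                p = np.zeros(len(otus))
                p[otu_taxon_idx < n_comm] = w_otu / total
                if c_rate > 0 and pool_otu.sum() > 0:
                    p = (1.0 - c_rate) * p + c_rate * pool_otu
                p = p / p.sum()
                depth = (scenario.library_size if scenario.fixed_depth
                         else int(rng.poisson(scenario.library_size)))
                table[:, col] = rng.multinomial(depth, p)
                col += 1
        for _ in control_samples:
            if pool_otu.sum() > 0 and ctrl_depth > 0:
                table[:, col] = rng.multinomial(ctrl_depth, pool_otu)
            col += 1
        counts[locus] = pd.DataFrame(
            table, index=otus, columns=field_samples + control_samples)

    corrupt_samples: list[str] = []
    if scenario.corrupt_timepoint is not None:
        sid = f"t{scenario.corrupt_timepoint}_r1"
        corrupt_samples.append(sid)
        comm_otus = np.flatnonzero(otu_taxon_idx < n_comm)
        for locus in scenario.loci:
            subset = rng.choice(comm_otus, size=max(2, len(comm_otus) // 10),
                                replace=False)
            p = np.zeros(len(otus))
            p[subset] = rng.dirichlet(np.ones(len(subset)))
            counts[locus][sid] = rng.multinomial(scenario.library_size, p)

    truth = {
        "module_truth": dict(latent.module_truth),
        "archetype_peaks": dict(latent.peaks),
        "hubs": dict(latent.hubs),
        "otu_to_taxon": otu_to_taxon,
        "efficiency": {taxon: {locus: float(E[i, li])
                               for li, locus in enumerate(scenario.loci)}
                       for i, taxon in enumerate(all_taxa)},
        "contaminants": terr_taxa,
        "env_links": env_links,
        "corrupt_samples": corrupt_samples,
    }
    return GeneratorOutput(counts, metadata, taxonomy, env_table, truth)


def simulate(scenario: CommunityScenario) -> GeneratorOutput:
    """End-to-end generation: latent dynamics, environment, reads."""
    latent = generate_latent_dynamics(scenario)
    return generate_reads(scenario, latent)


def write_generator_output(out: GeneratorOutput, directory: str | Path,
                           scenario: CommunityScenario | None = None) -> None:
    """Persist all generator tables as TSV plus a truth/scenario JSON/YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for locus, table in out.counts.items():
        table.to_csv(directory / f"counts_{locus}.tsv", sep="\t",
                     index_label="otu_id")
    out.metadata.to_csv(directory / "metadata.tsv", sep="\t")
    out.taxonomy.to_csv(directory / "taxonomy.tsv", sep="\t")
    out.environment.to_csv(directory / "environment.tsv", sep="\t")
    with open(directory / "truth.json", "w") as fh:
        json.dump(out.truth, fh, indent=2, sort_keys=True)
    if scenario is not None:
        import yaml

        with open(directory / "scenario.yaml", "w") as fh:
            yaml.safe_dump(scenario.to_dict(), fh, sort_keys=True)
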