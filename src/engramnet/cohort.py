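"""Synthetic BOLD-like cohorts with planted network structure.

Generates per-animal ROI time series whose Spearman correlation matrices
carry a known block (community) structure, a group-specific boost of
cross-community coupling at designated hub regions after a simulated
injection, and extinction-learning behavior scores linked to each
animal's planted hub strength.  Every downstream stage of the pipeline
can therefore be tested against ground truth without any imaging data.

The generative model is a latent-factor model: each latent community c
has a white-noise factor ``f_c(t)``; a region r in community c emits

    x_r(t) = w * f_c(t) + g * f_glob(t) + sum_{c' != c} k_r * f_c'(t) + e(t)

with independent Gaussian noise ``e``.  Cross-loadings ``k_r`` are zero
for ordinary regions, fixed for two connector regions (these keep group
networks integrated, as association cortices and midline relays do in
real brains), and present at baseline for the hub regions toward the
thalamic relay community.  The reactivation boost multiplies the hub
cross-loadings in post-injection bins, so the planted group difference
lives in edge *weights* at essentially unchanged edge sets and degree
sequences: the boosted mutual and relay coupling concentrates the
leading eigenvector on the hub triad, while in the control condition a
more strongly self-coupled ventral module carries the dominant
eigenvector and the hubs sit mid-scale.  No hemodynamic convolution or
autocorrelation is applied
(the analysis consumes rank correlations only); an AR(1) coefficient is
available for sensitivity checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .networks import RoiTimeSeries

__all__ = [
    "DEFAULT_REGIONS",
    "DEFAULT_COMMUNITIES",
    "DEFAULT_HUB_REGIONS",
    "DEFAULT_CONNECTOR_TARGETS",
    "DEFAULT_HUB_TARGETS",
    "CohortConfig",
    "generate_cohort",
    "generate_toy_graph",
]

#: The 21 regions of interest of the brain-wide panel: dorsal and ventral
#: hippocampal subfields, subiculum/postsubiculum, midline thalamic nuclei,
#: prefrontal and cingulate areas, retrosplenial subdivisions and posterior
#: parietal cortex.
DEFAULT_REGIONS: tuple[str, ...] = (
    "dDG", "dCA3", "dCA1", "vDG", "vCA3", "vCA1", "SUBd", "PoS",
    "RE", "LDT", "PVT", "NAc", "ORB", "IL", "PrL", "aRSP", "iRSP",
    "pRSP", "aACC", "pACC", "PPC",
)

#: Latent community assignment used by the generator: a dorsal-hippocampal
#: module, a ventral-hippocampal module, a prefrontal module, and a small
#: midline relay module.  This mirrors the kind of modular organisation the
#: analysis is meant to recover; it is ground truth for tests, not a claim
#: about anatomy.
DEFAULT_COMMUNITIES: dict[str, str] = {
    "dDG": "dorsal", "dCA3": "dorsal", "dCA1": "dorsal",
    "PPC": "dorsal", "aRSP": "dorsal", "LDT": "dorsal",
    "vDG": "ventral", "vCA3": "ventral", "vCA1": "ventral",
    "SUBd": "ventral", "PoS": "ventral", "pRSP": "ventral",
    "ORB": "prefrontal", "IL": "prefrontal", "PrL": "prefrontal",
    "NAc": "prefrontal", "aACC": "prefrontal", "pACC": "prefrontal",
    "RE": "relay", "PVT": "relay", "iRSP": "relay",
}

#: Regions whose coupling is boosted by ensemble reactivation.
DEFAULT_HUB_REGIONS: tuple[str, ...] = ("dDG", "dCA3", "dCA1")

#: Foreign communities the hub regions couple to (in both groups; the
#: reactivation boost strengthens these loadings without changing which
#: pairs correlate, i.e. the effect lives in edge weights, not degrees).
DEFAULT_HUB_TARGETS: tuple[str, ...] = ("relay",)

#: Connector regions with fixed cross-community loadings in both groups;
#: they keep the group networks integrated the way association cortices
#: and midline relays do.
DEFAULT_CONNECTOR_TARGETS: dict[str, tuple[str, ...]] = {
    "PPC": ("ventral", "relay"),
    "RE": ("dorsal", "prefrontal"),
}

GROUP_CONTROL = "control"
GROUP_REACTIVATION = "reactivation"


@dataclass
class CohortConfig:
    """Parameters of a synthetic two-group cohort.

    Parameters
    ----------
    seed
        Master seed; identical seeds give byte-identical cohorts.
    n_per_group
        Animals per group (control / reactivation).
    samples_per_bin, n_bins
        15 min of scanning at a repetition time of 1 s gives 900 samples
        per bin; four bins cover baseline (T1) plus three post-injection
        windows (T2-T4).
    hub_gain
        Dimensionless boost of the hub regions' cross-community loading,
        applied in the reactivation group from the second bin onward.
        0 disables the planted effect entirely.
    noise_sd
        Standard deviation of the region-level white noise.
    behavior_coupling
        Slope (percentage points per unit of planted hub strength)
        linking an animal's realised hub gain to its late
        extinction-learning performance.
    hub_base_cross, connector_cross, within_loading, global_loading
        Loadings of the latent-factor model; defaults put
        within-community Spearman correlations near 0.5-0.6, connector
        and baseline hub cross-correlations near 0.2 (comfortably above
        the Bonferroni threshold over 900 samples, so the edge sets of
        the two groups match and the planted contrast is carried by
        weights), and unrelated cross-community pairs near 0.04 (well
        below threshold) -- roughly the correlation regime of
        band-passed anesthetized-rodent BOLD.
    community_loadings
        Per-community overrides of ``within_loading``; the default makes
        the ventral module the most cohesive one, which anchors the
        dominant eigenvector in the control (resting-state-like)
        networks.
    hub_strength_sd
        Between-animal spread of the realised hub gain (multiplicative,
        around 1).
    ar_coef
        Optional AR(1) coefficient for factors and noise (0 = white).
    """

    seed: int = 0
    n_per_group: int = 8
    region_names: tuple[str, ...] = DEFAULT_REGIONS
    community_assignment: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMMUNITIES))
    hub_regions: tuple[str, ...] = DEFAULT_HUB_REGIONS
    hub_target_communities: tuple[str, ...] = DEFAULT_HUB_TARGETS
    connector_targets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CONNECTOR_TARGETS))
    samples_per_bin: int = 900
    n_bins: int = 4
    hub_gain: float = 1.5
    noise_sd: float = 1.0
    behavior_coupling: float = 12.0
    within_loading: float = 1.0
    community_loadings: dict[str, float] = field(
        default_factory=lambda: {"ventral": 1.3})
    global_loading: float = 0.3
    hub_base_cross: float = 0.4
    connector_cross: float = 0.4
    hub_strength_sd: float = 0.25
    ar_coef: float = 0.0
    chance_level: float = 50.0
    behavior_noise_sd: float = 5.0
    n_behavior_blocks: int = 3
    behavior_session: str = "EL2"

    def __post_init__(self) -> None:
        if self.samples_per_bin <= 0:
            raise ValueError("samples_per_bin must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")
        if self.hub_gain < 0:
            raise ValueError("hub_gain must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.hub_regions) - set(self.region_names)
        if unknown:
            raise ValueError(f"hub_regions not in region panel: {sorted(unknown)}")
        unknown = set(self.connector_targets) - set(self.region_names)
        if unknown:
            raise ValueError(
                f"connector regions not in region panel: {sorted(unknown)}")
        missing = set(self.region_names) - set(self.community_assignment)
        if missing:
            raise ValueError(f"regions without a community: {sorted(missing)}")
        comms = set(self.community_assignment.values())
        bad = set(self.hub_target_communities) - comms
        if bad:
            raise ValueError(f"unknown hub target communities: {sorted(bad)}")

    @property
    def communities(self) -> list[str]:
        seen: list[str] = []
        for r in self.region_names:
            c = self.community_assignment[r]
            if c not in seen:
                seen.append(c)
        return seen


def _ar1(white: np.ndarray, phi: float) -> np.ndarray:
    """Turn white noise into AR(1) series along the last axis (unit variance)."""
    if phi == 0.0:
        return white
    out = np.empty_like(white)
    out[..., 0] = white[..., 0]
    for t in range(1, white.shape[-1]):
        out[..., t] = phi * out[..., t - 1] + white[..., t]
    return out * np.sqrt(1.0 - phi**2)


def _loading_matrix(config: CohortConfig, group: str, post_injection: bool,
                    hub_multiplier: float) -> np.ndarray:
    """Region x (communities + global) loading matrix for one animal/bin."""
    comms = config.communities
    n_r, n_c = len(config.region_names), len(comms)
    load = np.zeros((n_r, n_c + 1))
    c_index = {c: i for i, c in enumerate(comms)}
    hub_cross = config.hub_base_cross
    if group == GROUP_REACTIVATION and post_injection:
        hub_cross = config.hub_base_cross * (1.0 + config.hub_gain * hub_multiplier)
    for i, r in enumerate(config.region_names):
        own_comm = config.community_assignment[r]
        own = c_index[own_comm]
        load[i, own] = config.community_loadings.get(
            own_comm, config.within_loading)
        for target in config.connector_targets.get(r, ()):
            if target != own_comm:
                load[i, c_index[target]] = config.connector_cross
        if r in config.hub_regions:
            for target in config.hub_target_communities:
                if target != own_comm:
                    load[i, c_index[target]] = hub_cross
        load[i, n_c] = config.global_loading
    return load


def generate_cohort(config: CohortConfig) -> tuple[list[RoiTimeSeries], pd.DataFrame]:
    """Generate a two-group cohort of ROI time series plus behavior scores.

    Returns
    -------
    timeseries : list of RoiTimeSeries
        ``2 * n_per_group`` animals; group labels ``"control"`` and
        ``"reactivation"``.  Each carries its planted per-animal hub
        strength in ``attrs["hub_strength"]`` (ground truth for tests).
    behavior : pandas.DataFrame
        Columns ``animal_id, group, session, block_index, percent_correct``,
        one row per animal per extinction-learning block.  Control
        animals decay toward chance across blocks; reactivation animals
        hold a preference whose final-block level increases with their
        planted hub strength by ``behavior_coupling`` points per unit.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.samples_per_bin * config.n_bins
    comms = config.communities
    n_c = len(comms)

    animals: list[RoiTimeSeries] = []
    behavior_rows: list[dict] = []
    bin_edges = [b * config.samples_per_bin for b in range(config.n_bins + 1)]

    for group in (GROUP_CONTROL, GROUP_REACTIVATION):
        for k in range(config.n_per_group):
            animal_id = f"{group[:4]}{k + 1:02d}"
            multiplier = float(np.clip(
                1.0 + config.hub_strength_sd * rng.standard_normal(), 0.0, None))
            hub_strength = (config.hub_gain * multiplier
                            if group == GROUP_REACTIVATION else 0.0)

            samples = np.empty((len(config.region_names), n_total))
            for b in range(config.n_bins):
                factors = _ar1(
                    rng.standard_normal((n_c + 1, config.samples_per_bin)),
                    config.ar_coef)
                noise = config.noise_sd * _ar1(
                    rng.standard_normal(
                        (len(config.region_names), config.samples_per_bin)),
                    config.ar_coef)
                load = _loading_matrix(config, group, post_injection=b >= 1,
                                       hub_multiplier=multiplier)
                sl = slice(bin_edges[b], bin_edges[b + 1])
                samples[:, sl] = load @ factors + noise

            ts = RoiTimeSeries(
                animal_id=animal_id, group=group,
                region_names=list(config.region_names),
                samples=samples, bin_edges=list(bin_edges),
                attrs={"hub_strength": hub_strength,
                       "hub_multiplier": multiplier},
            )
            animals.append(ts)

            # Behavior: % correct per extinction block.  Controls start above
            # chance and extinguish; reactivated animals persist, with the
            # final ("late EL") block coupled to planted hub strength.
            for block in range(1, config.n_behavior_blocks + 1):
                late = block == config.n_behavior_blocks
                if group == GROUP_CONTROL:
                    start = config.chance_level + 15.0
                    frac = (block - 1) / max(config.n_behavior_blocks - 1, 1)
                    mean = start - 15.0 * frac
                else:
                    mean = config.chance_level + 2.0
                    if late:
                        mean += config.behavior_coupling * hub_strength
                    else:
                        mean += config.behavior_coupling * config.hub_gain
                pc = float(np.clip(
                    mean + config.behavior_noise_sd * rng.standard_normal(),
                    0.0, 100.0))
                behavior_rows.append({
                    "animal_id": animal_id, "group": group,
                    "session": config.behavior_session,
                    "block_index": block, "percent_correct": pc,
                })

    behavior = pd.DataFrame(behavior_rows)
    return animals, behavior


def generate_toy_graph(kind: str, n: int = 4, weight: float = 1.0,
                       p_in: float = 0.9, p_out: float = 0.05,
                       n_blocks: int = 3, seed: int | None = None) -> nx.Graph:
    """Small analytic graphs with known properties, used as oracle fixtures.

    ``kind`` is one of ``complete``, ``star``, ``path``, ``ring`` or
    ``planted_partition``.  All edges carry the uniform ``weight``.  For
    ``planted_partition`` the n nodes are split into ``n_blocks`` equal
    groups, an edge appears within a group with probability ``p_in`` and
    between groups with ``p_out``; planted labels are stored on the
    nodes under ``"community"``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "ring":
        g = nx.cycle_graph(n)
    elif kind == "planted_partition":
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        labels = {i: i * n_blocks // n for i in range(n)}
        nx.set_node_attributes(g, labels, "community")
        for i, j in itertools.combinations(range(n), 2):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                g.add_edge(i, j)
    else:
        raise ValueError(f"unknown toy-graph kind: {kind!r}")
    nx.set_edge_attributes(g, weight, "weight")
    g.graph["provenance"] = f"toy:{kind}"
    return g
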