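"""Modular small-world network construction.

Builds the synaptic substrate for the spiking simulations: Watts-Strogatz
small-world modules of excitatory neurons, sparsely rewired between each
other, plus a random-graph pool of inhibitory neurons that receives focal
excitation and projects diffuse inhibition.  Every construction path
respects Dale's law (a neuron's outgoing synapses all share one sign) and
annotates each synapse with an integer axonal conduction delay.

Weight-matrix convention: ``weights[post, pre]`` is the synaptic strength
from presynaptic neuron ``pre`` onto postsynaptic neuron ``post``, so the
sign of a *column* is fixed by the presynaptic neuron's type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "GraphSpec",
    "ModularNetworkConfig",
    "WeightedNetwork",
    "generate_watts_strogatz",
    "build_modular_swn",
    "assign_delays",
    "save_network",
    "load_network",
    "write_edge_list",
    "read_edge_list",
]

#: module label used for the inhibitory pool (excitatory modules are 1..M)
INHIBITORY_MODULE = 0


@dataclass(frozen=True)
class GraphSpec:
    """Parameters of a single Watts-Strogatz small-world graph.

    Attributes
    ----------
    n_nodes : int
        Number of nodes N.
    mean_degree : int
        Mean degree K; must be even and < N.  The ring lattice joins each
        node to K/2 neighbours on each side, giving exactly N*K/2 edges.
    rewiring_prob : float
        Probability beta in [0, 1] of rewiring each lattice edge.
    seed : int
        RNG seed for the rewiring draws.
    """

    n_nodes: int
    mean_degree: int
    rewiring_prob: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.mean_degree % 2 != 0:
            raise ValueError(f"mean_degree must be even, got {self.mean_degree}")
        if not 0 < self.mean_degree < self.n_nodes:
            raise ValueError("mean_degree must satisfy 0 < K < n_nodes")
        if not 0.0 <= self.rewiring_prob <= 1.0:
            raise ValueError("rewiring_prob must lie in [0, 1]")


@dataclass(frozen=True)
class ModularNetworkConfig:
    """Configuration of the modular excitatory/inhibitory network.

    Defaults follow the standard modular small-world cortical model:
    M = 8 modules of 100 excitatory neurons (indices 0..799), one pool of
    200 inhibitory neurons (indices 800..999), mean degree 6 within each
    module, and intra/inter rewiring probabilities of 0.1.

    ``weight_scales`` carry the sign of each connection block; Dale's law
    requires EE and EI positive, IE and II negative.  Magnitudes of
    individual synapses are uniform(0, 1) draws times the block scale.
    """

    n_modules: int = 8
    module_size: int = 100
    n_inhibitory: int = 200
    mean_degree: int = 6
    intra_rewiring: float = 0.1
    inter_rewiring: float = 0.1
    directed: bool = True
    weight_scales: dict = field(
        default_factory=lambda: {"EE": 17.0, "EI": 50.0, "IE": -2.0, "II": -1.0}
    )
    max_delay_ms: int = 20
    n_ei_afferents: int = 4
    seed: int = 0

    @property
    def n_excitatory(self) -> int:
        return self.n_modules * self.module_size

    @property
    def n_total(self) -> int:
        return self.n_excitatory + self.n_inhibitory

    def __post_init__(self) -> None:
        if min(self.n_modules, self.module_size, self.n_inhibitory) < 1:
            raise ValueError("n_modules, module_size, n_inhibitory must be positive")
        for key in ("EE", "EI", "IE", "II"):
            if key not in self.weight_scales:
                raise ValueError(f"weight_scales missing block {key!r}")
        if self.weight_scales["EE"] <= 0 or self.weight_scales["EI"] <= 0:
            raise ValueError("Dale's law: EE and EI weight scales must be positive")
        if self.weight_scales["IE"] >= 0 or self.weight_scales["II"] >= 0:
            raise ValueError("Dale's law: IE and II weight scales must be negative")
        if self.max_delay_ms < 1:
            raise ValueError("max_delay_ms must be >= 1")
        if not 0.0 <= self.intra_rewiring <= 1.0:
            raise ValueError("intra_rewiring must lie in [0, 1]")
        if not 0.0 <= self.inter_rewiring <= 1.0:
            raise ValueError("inter_rewiring must lie in [0, 1]")


@dataclass
class WeightedNetwork:
    """Signed, delay-annotated synaptic weight matrix with labels.

    Attributes
    ----------
    weights : (N, N) float array
        ``weights[post, pre]``; zero where no synapse exists; zero diagonal.
    delays : (N, N) int array
        Conduction delay in ms; nonzero exactly where a synapse exists.
    neuron_type : (N,) array of str
        "excitatory" or "inhibitory".
    module_id : (N,) int array
        1..M for excitatory modules, ``INHIBITORY_MODULE`` (0) for the pool.
    directed : bool
        Whether the excitatory/inhibitory within-type blocks are symmetric.
    """

    weights: np.ndarray
    delays: np.ndarray
    neuron_type: np.ndarray
    module_id: np.ndarray
    directed: bool = True

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def excitatory_mask(self) -> np.ndarray:
        return self.neuron_type == "excitatory"

    @property
    def n_modules(self) -> int:
        return int(self.module_id.max())

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        w, d = self.weights, self.delays
        n = self.n_neurons
        if w.shape != (n, n) or d.shape != (n, n):
            raise ValueError("weights and delays must both be N x N")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops present: diagonal of weights not zero")
        if np.any((d != 0) != (w != 0)):
            raise ValueError("delays must be nonzero exactly on existing edges")
        exc = self.excitatory_mask
        if np.any(w[:, exc] < 0) or np.any(w[:, ~exc] > 0):
            raise ValueError("Dale's law violated: outgoing sign not uniform")


def generate_watts_strogatz(spec: GraphSpec) -> nx.Graph:
    """Generate a Watts-Strogatz small-world graph.

    Starts from a ring lattice in which every node is joined to its K/2
    nearest neighbours on each side, then rewires each lattice edge with
    probability beta to a uniformly chosen non-duplicate, non-self target.
    Rewiring preserves the edge count, so the result always has exactly
    N*K/2 edges; on average beta*N*K/2 of them are non-lattice edges.

    At beta = 0 the graph is the regular ring lattice (local clustering
    3(K-2)/(4(K-1))); at beta = 1 it statistically resembles an
    Erdos-Renyi random graph of the same mean degree.
    """
    return nx.watts_strogatz_graph(
        spec.n_nodes, spec.mean_degree, spec.rewiring_prob, seed=spec.seed
    )


def _ws_edge_pairs(n: int, k: int, beta: float, rng: np.random.Generator) -> list:
    """Watts-Strogatz edge pairs using a shared numpy Generator."""
    seed = int(rng.integers(0, 2**31 - 1))
    g = generate_watts_strogatz(GraphSpec(n, k, beta, seed=seed))
    return list(g.edges())


def build_modular_swn(config: ModularNetworkConfig) -> WeightedNetwork:
    """Assemble the modular small-world excitatory/inhibitory network.

    Construction:

    1. Each of the M excitatory modules is an independent Watts-Strogatz
       graph (``module_size`` nodes, mean degree K, rewiring
       ``intra_rewiring``).
    2. Each intra-module edge is then independently rewired with
       probability ``inter_rewiring`` to a uniformly chosen neuron in a
       *different* excitatory module (edge count preserved), producing the
       sparse long-range connections between modules.
    3. Every inhibitory neuron receives focal excitation from
       ``n_ei_afferents`` distinct excitatory neurons of one randomly
       chosen module (EI block) and projects diffuse inhibition to every
       other neuron outside the inhibitory pool (IE block).
    4. The inhibitory pool itself is an Erdos-Renyi random graph with mean
       degree K (II block).

    Weights are uniform(0, 1) magnitudes times the signed block scales
    (defaults EE +17, EI +50, IE -2, II -1); the diagonal is zero.  With
    ``directed=False`` the within-type blocks (EE, II) are symmetric in
    both weight and, after :func:`assign_delays`, delay; mixed E-I blocks
    are structural projections whose signs Dale's law fixes, so they are
    unaffected by the flag.  Call :func:`assign_delays` (done here) to
    annotate conduction delays.
    """
    rng = np.random.default_rng(config.seed)
    m, nm, ni = config.n_modules, config.module_size, config.n_inhibitory
    ne = config.n_excitatory
    n = config.n_total
    ws = config.weight_scales

    module_id = np.empty(n, dtype=np.int64)
    module_id[ne:] = INHIBITORY_MODULE
    neuron_type = np.empty(n, dtype=object)
    neuron_type[:ne] = "excitatory"
    neuron_type[ne:] = "inhibitory"
    neuron_type = neuron_type.astype(str)

    # --- EE: Watts-Strogatz module graphs + inter-module rewiring -------
    edge_set: set[tuple[int, int]] = set()  # unordered pairs (u < v)
    for mod in range(m):
        off = mod * nm
        module_id[off : off + nm] = mod + 1
        for u, v in _ws_edge_pairs(nm, config.mean_degree, config.intra_rewiring, rng):
            a, b = sorted((u + off, v + off))
            edge_set.add((a, b))

    if m > 1 and config.inter_rewiring > 0:
        for pair in list(edge_set):
            if rng.random() >= config.inter_rewiring:
                continue
            u, v = pair
            # move endpoint v to a uniformly chosen node of another module
            keep = u if rng.random() < 0.5 else v
            for _ in range(64):  # resample on duplicates
                w = int(rng.integers(0, ne))
                if module_id[w] == module_id[keep]:
                    continue
                cand = (min(keep, w), max(keep, w))
                if cand not in edge_set:
                    edge_set.discard(pair)
                    edge_set.add(cand)
                    break

    weights = np.zeros((n, n), dtype=np.float64)

    def _pair_weights(pairs: np.ndarray, scale: float, symmetric: bool) -> None:
        """Fill both orientations of unordered pairs with drawn magnitudes."""
        if len(pairs) == 0:
            return
        u, v = pairs[:, 0], pairs[:, 1]
        mag = rng.uniform(0.0, 1.0, size=len(pairs))
        weights[v, u] = scale * mag
        if symmetric:
            weights[u, v] = scale * mag
        else:
            weights[u, v] = scale * rng.uniform(0.0, 1.0, size=len(pairs))

    ee_pairs = np.array(sorted(edge_set), dtype=np.int64).reshape(-1, 2)
    _pair_weights(ee_pairs, ws["EE"], symmetric=not config.directed)

    # --- EI: focal excitation onto each inhibitory neuron ---------------
    for i in range(ne, n):
        mod = int(rng.integers(0, m))
        src = rng.choice(nm, size=min(config.n_ei_afferents, nm), replace=False)
        weights[i, src + mod * nm] = ws["EI"] * rng.uniform(0.0, 1.0, size=len(src))

    # --- IE: diffuse inhibition onto all excitatory neurons -------------
    weights[:ne, ne:] = ws["IE"] * rng.uniform(0.0, 1.0, size=(ne, ni))

    # --- II: Erdos-Renyi pool with mean degree K ------------------------
    p_ii = min(1.0, config.mean_degree / max(ni - 1, 1))
    iu, iv = np.triu_indices(ni, k=1)
    pick = rng.random(len(iu)) < p_ii
    ii_pairs = np.stack([iu[pick] + ne, iv[pick] + ne], axis=1)
    _pair_weights(ii_pairs, ws["II"], symmetric=not config.directed)

    np.fill_diagonal(weights, 0.0)

    net = WeightedNetwork(
        weights=weights,
        delays=np.zeros((n, n), dtype=np.int64),
        neuron_type=neuron_type,
        module_id=module_id,
        directed=config.directed,
    )
    net = assign_delays(net, config.max_delay_ms, seed=int(rng.integers(0, 2**31 - 1)))
    net.validate()
    return net


def assign_delays(
    network: WeightedNetwork, max_delay_ms: int, seed: int = 0
) -> WeightedNetwork:
    """Annotate existing synapses with integer conduction delays (ms).

    Excitatory-to-excitatory synapses model axons of varying length and
    get delays drawn uniformly from {1, ..., max_delay_ms}; all synapses
    involving inhibitory neurons (EI, IE, II) are local and get 1 ms.
    Delays are stored only on existing edges (0 elsewhere, never
    consulted); for undirected networks the EE delays are symmetric.
    """
    if max_delay_ms < 1:
        raise ValueError("max_delay_ms must be >= 1")
    rng = np.random.default_rng(seed)
    exc = network.excitatory_mask
    present = network.weights != 0

    delays = np.zeros_like(network.delays)
    delays[present] = 1  # every synapse involving an inhibitory neuron

    ee = present & np.outer(exc, exc)
    if network.directed:
        delays[ee] = rng.integers(1, max_delay_ms + 1, size=int(ee.sum()))
    else:
        upper = ee & (np.arange(len(exc))[:, None] < np.arange(len(exc))[None, :])
        draw = rng.integers(1, max_delay_ms + 1, size=int(upper.sum()))
        d = np.zeros_like(delays)
        d[upper] = draw
        d = d + d.T
        delays[ee] = d[ee]

    network.delays = delays
    return network


# ---------------------------------------------------------------------------
# persistence


def save_network(network: WeightedNetwork, path: str) -> None:
    """Save a network to a .npz array container."""
    np.savez_compressed(
        path,
        weights=network.weights,
        delays=network.delays,
        neuron_type=network.neuron_type.astype("U10"),
        module_id=network.module_id,
        directed=np.array(network.directed),
    )


def load_network(path: str) -> WeightedNetwork:
    with np.load(path, allow_pickle=False) as f:
        return WeightedNetwork(
            weights=f["weights"],
            delays=f["delays"],
            neuron_type=f["neuron_type"].astype(str),
            module_id=f["module_id"],
            directed=bool(f["directed"]),
        )


def write_edge_list(network: WeightedNetwork, path: str) -> None:
    """Write `pre post weight delay_ms` text plus a JSON label sidecar."""
    post, pre = np.nonzero(network.weights)
    with open(path, "w") as fh:
        fh.write("# pre post weight delay_ms\n")
        for i, j in zip(pre, post):
            fh.write(
                f"{i} {j} {network.weights[j, i]:.17g} {network.delays[j, i]}\n"
            )
    sidecar = {
        "n_neurons": network.n_neurons,
        "directed": network.directed,
        "neuron_type": network.neuron_type.tolist(),
        "module_id": network.module_id.tolist(),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def read_edge_list(path: str) -> WeightedNetwork:
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    n = sidecar["n_neurons"]
    weights = np.zeros((n, n))
    delays = np.zeros((n, n), dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            try:
                pre_s, post_s, w_s, d_s = line.split()
                i, j = int(pre_s), int(post_s)
                weights[j, i] = float(w_s)
                delays[j, i] = int(d_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed edge row") from exc
    return WeightedNetwork(
        weights=weights,
        delays=delays,
        neuron_type=np.asarray(sidecar["neuron_type"], dtype=str),
        module_id=np.asarray(sidecar["module_id"], dtype=np.int64),
        directed=sidecar["directed"],
    )
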