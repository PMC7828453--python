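"""Decision tree structures (DTS) with neural-network judgment nodes.

A DTS is a small fixed tree whose internal nodes are independently trained
networks; an instance descends from the root, taking the argmax branch at each
node, until it reaches a leaf naming a single locomotion mode.  Two built-in
five-node topologies are provided:

* **DTS-A** (two layers): the root splits the nine modes into the four
  similarity categories — walking {SLW, MLW, FLW}, ramps {RD, RA}, stairs
  {SD, SA}, static {Sit, Stand} — and four children resolve each category.
* **DTS-B** (four-layer chain): node 1 separates {Sit, Stand} from the rest;
  node 2 Sit vs Stand; node 3 peels off SD and SA from the moving modes;
  node 4 peels off RA and RD; node 5 resolves the three walking speeds.

DTS-B's default hidden sizes (10, 30, 30, 60, 40) are the structure-optimized
per-node neuron counts; DTS-A and the flat 9-way network default to 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .data import MODES, Dataset, MinMaxNormalizer
from .ibpnn import NetworkParams, TrainConfig, TrainHistory, forward_batch, init_params, train
from .abc_optimizer import ABCConfig, abc_init_network

DEFAULT_HIDDEN = 100
DTS_B_HIDDEN = (10, 30, 30, 60, 40)


@dataclass
class Branch:
    """One output of a judgment node: either a child node id or a leaf set."""

    child: str | None = None
    leaf: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if (self.child is None) == (self.leaf is None):
            raise ValueError("a branch is either a child reference or a leaf set")
        if self.leaf is not None:
            self.leaf = frozenset(self.leaf)


@dataclass
class DTSNodeSpec:
    node_id: str
    hidden: int
    branches: list[Branch]

    @property
    def n_outputs(self) -> int:
        return len(self.branches)


@dataclass
class DTSSpec:
    """Validated tree topology mapping the nine modes to unique leaves."""

    name: str
    root: str
    nodes: dict[str, DTSNodeSpec]

    def __post_init__(self) -> None:
        if self.root not in self.nodes:
            raise ValueError(f"root node {self.root!r} not defined")
        seen_modes: list[str] = []
        visited: set[str] = set()

        def visit(node_id: str) -> None:
            if node_id in visited:
                raise ValueError(f"node {node_id!r} reached twice (cycle or shared child)")
            visited.add(node_id)
            node = self.nodes.get(node_id)
            if node is None:
                raise ValueError(f"branch references undefined node {node_id!r}")
            leaf_modes: set[str] = set()
            for br in node.branches:
                if br.child is not None:
                    visit(br.child)
                else:
                    if leaf_modes & br.leaf:
                        raise ValueError(f"node {node_id!r} has overlapping leaf sets")
                    leaf_modes |= br.leaf
            seen_modes.extend(leaf_modes)

        visit(self.root)
        if visited != set(self.nodes):
            raise ValueError(f"unreachable nodes: {sorted(set(self.nodes) - visited)}")
        if sorted(seen_modes) != sorted(MODES):
            raise ValueError(
                f"leaves must cover each of the 9 modes exactly once, got {sorted(seen_modes)}"
            )

    def subtree_modes(self, node_id: str) -> frozenset[str]:
        """All modes reachable under a node."""
        node = self.nodes[node_id]
        out: set[str] = set()
        for br in node.branches:
            out |= br.leaf if br.leaf is not None else self.subtree_modes(br.child)
        return frozenset(out)

    def depth(self) -> int:
        def d(node_id: str) -> int:
            node = self.nodes[node_id]
            children = [d(br.child) for br in node.branches if br.child is not None]
            return 1 + (max(children) if children else 0)

        return d(self.root)

    # -- YAML round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "root": self.root,
            "nodes": [
                {
                    "id": nid,
                    "hidden": node.hidden,
                    "branches": [
                        {"class": i, **({"child": br.child} if br.child else {"leaf": sorted(br.leaf)})}
                        for i, br in enumerate(node.branches)
                    ],
                }
                for nid, node in self.nodes.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DTSSpec":
        nodes = {}
        for nd in d["nodes"]:
            branches = [None] * len(nd["branches"])
            for br in nd["branches"]:
                branches[br["class"]] = Branch(child=br.get("child"), leaf=br.get("leaf"))
            nodes[nd["id"]] = DTSNodeSpec(nd["id"], int(nd["hidden"]), branches)
        return cls(d["name"], d["root"], nodes)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "DTSSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def builtin_spec(name: str, hidden: tuple[int, ...] | None = None) -> DTSSpec:
    """The two canonical five-node topologies ("DTS-A", "DTS-B")."""
    key = name.upper().replace("_", "-")
    if key == "DTS-A":
        h = hidden or (DEFAULT_HIDDEN,) * 5
        nodes = {
            "node1": DTSNodeSpec("node1", h[0], [
                Branch(child="node2"), Branch(child="node3"),
                Branch(child="node4"), Branch(child="node5"),
            ]),
            "node2": DTSNodeSpec("node2", h[1], [
                Branch(leaf={"SLW"}), Branch(leaf={"MLW"}), Branch(leaf={"FLW"}),
            ]),
            "node3": DTSNodeSpec("node3", h[2], [Branch(leaf={"RD"}), Branch(leaf={"RA"})]),
            "node4": DTSNodeSpec("node4", h[3], [Branch(leaf={"SD"}), Branch(leaf={"SA"})]),
            "node5": DTSNodeSpec("node5", h[4], [Branch(leaf={"Sit"}), Branch(leaf={"Stand"})]),
        }
        return DTSSpec("DTS-A", "node1", nodes)
    if key == "DTS-B":
        h = hidden or DTS_B_HIDDEN
        nodes = {
            "node1": DTSNodeSpec("node1", h[0], [Branch(child="node2"), Branch(child="node3")]),
            "node2": DTSNodeSpec("node2", h[1], [Branch(leaf={"Sit"}), Branch(leaf={"Stand"})]),
            "node3": DTSNodeSpec("node3", h[2], [
                Branch(leaf={"SD"}), Branch(leaf={"SA"}), Branch(child="node4"),
            ]),
            "node4": DTSNodeSpec("node4", h[3], [
                Branch(leaf={"RA"}), Branch(leaf={"RD"}), Branch(child="node5"),
            ]),
            "node5": DTSNodeSpec("node5", h[4], [
                Branch(leaf={"SLW"}), Branch(leaf={"MLW"}), Branch(leaf={"FLW"}),
            ]),
        }
        return DTSSpec("DTS-B", "node1", nodes)
    raise ValueError(f"unknown built-in DTS {name!r}; expected 'DTS-A' or 'DTS-B'")


def relabel_for_node(ds: Dataset, spec: DTSSpec, node_id: str) -> Dataset:
    """Map 9-way labels to node-local branch indices.

    Instances whose mode does not fall under the node's subtree are excluded
    (an explicit "others" class exists only where the topology declares a
    branch for it). Modes absent from the whole spec are an error.
    """
    node = spec.nodes[node_id]
    mode_to_class: dict[str, int] = {}
    for i, br in enumerate(node.branches):
        modes = br.leaf if br.leaf is not None else spec.subtree_modes(br.child)
        for mode in modes:
            mode_to_class[mode] = i
    unknown = set(map(str, ds.labels)) - set(MODES)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not present in the mode set")
    keep = np.array([str(m) in mode_to_class for m in ds.labels])
    y = np.array([mode_to_class[str(m)] for m in ds.labels[keep]], dtype=int)
    return replace(ds, X=ds.X[keep], labels=ds.labels[keep], y=y, n_classes=node.n_outputs)


@dataclass
class TrainedDTS:
    """A topology plus one trained network per judgment node."""

    spec: DTSSpec
    params: dict[str, NetworkParams]
    histories: dict[str, TrainHistory] = field(default_factory=dict)
    normalizer: MinMaxNormalizer | None = None

    def __post_init__(self) -> None:
        for nid, node in self.spec.nodes.items():
            p = self.params.get(nid)
            if p is None:
                raise ValueError(f"node {nid!r} has no trained parameters")
            if isinstance(p, NetworkParams) and p.l != node.n_outputs:
                raise ValueError(f"node {nid!r}: network has {p.l} outputs, spec declares {node.n_outputs}")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.spec.save(directory / "spec.yaml")
        for nid, p in self.params.items():
            p.save(directory / f"{nid}.json")
        if self.normalizer is not None:
            (directory / "normalizer.json").write_text(json.dumps(self.normalizer.to_dict()))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedDTS":
        directory = Path(directory)
        spec = DTSSpec.load(directory / "spec.yaml")
        params = {nid: NetworkParams.load(directory / f"{nid}.json") for nid in spec.nodes}
        norm_path = directory / "normalizer.json"
        normalizer = (
            MinMaxNormalizer.from_dict(json.loads(norm_path.read_text())) if norm_path.exists() else None
        )
        return cls(spec, params, normalizer=normalizer)


def train_dts(
    spec: DTSSpec,
    train_ds: Dataset,
    cfg: TrainConfig,
    abc_cfg: ABCConfig | None = None,
    input_dim: int | None = None,
) -> TrainedDTS:
    """Train every judgment node independently on its relabeled subset.

    Per-node seeds are derived deterministically from ``cfg.seed`` and the
    node's position in id order, so node training order is immaterial. With an
    ABC config, each node's initial parameters come from the bee-colony search
    instead of a plain uniform draw.
    """
    n = input_dim or train_ds.dim
    params: dict[str, NetworkParams] = {}
    histories: dict[str, TrainHistory] = {}
    for offset, nid in enumerate(sorted(spec.nodes)):
        node = spec.nodes[nid]
        sub = relabel_for_node(train_ds, spec, nid)
        if len(sub) == 0:
            raise ValueError(f"node {nid!r} received no training instances")
        node_seed = (cfg.seed * 131 + offset) % (2**31)
        node_cfg = replace(cfg, seed=node_seed)
        arch = (n, node.hidden, node.n_outputs)
        if abc_cfg is not None:
            abc_node_cfg = ABCConfig(**{**abc_cfg.__dict__, "dim": None, "seed": node_seed})
            p0 = abc_init_network(sub, arch, abc_node_cfg, node_cfg)
        else:
            p0 = init_params(*arch, init_range=cfg.init_range, seed=node_seed)
        params[nid], histories[nid] = train(p0, sub, node_cfg)
    return TrainedDTS(spec, params, histories)


def predict_dts(model: TrainedDTS, x: np.ndarray) -> str:
    """Route one normalized instance from the root to a single-mode leaf."""
    return predict_dts_batch(model, np.asarray(x, dtype=float)[None, :])[0]


def predict_dts_batch(model: TrainedDTS, X: np.ndarray) -> np.ndarray:
    """Vectorized hierarchical routing of a (N, n) batch."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0], dtype=object)

    def route(node_id: str, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        node = model.spec.nodes[node_id]
        p = model.params[node_id]
        # a node classifier is either trained network parameters or any
        # callable mapping a batch to per-branch scores (useful for oracles)
        scores = p(X[idx]) if callable(p) else forward_batch(p, X[idx])
        choice = np.argmax(scores, axis=1)
        for b, br in enumerate(node.branches):
            sel = idx[choice == b]
            if br.leaf is not None:
                if len(br.leaf) != 1:
                    raise ValueError(f"leaf at node {node_id!r} names {len(br.leaf)} modes")
                out[sel] = next(iter(br.leaf))
            else:
                route(br.child, sel)

    route(model.spec.root, np.arange(X.shape[0]))
    return out.astype(object)


def predict_flat(p: NetworkParams, x: np.ndarray) -> str:
    """9-way argmax readout in the frozen mode order."""
    return predict_flat_batch(p, np.asarray(x, dtype=float)[None, :])[0]


def predict_flat_batch(p: NetworkParams, X: np.ndarray) -> np.ndarray:
    if p.l != len(MODES):
        raise ValueError(f"flat classifier must have {len(MODES)} outputs, has {p.l}")
    idx = np.argmax(forward_batch(p, X), axis=1)
    return np.array([MODES[i] for i in idx], dtype=object)
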