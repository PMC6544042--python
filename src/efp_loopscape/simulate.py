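"""Synthetic data generator for the EF-P loop analysis.

Emulates the statistical structure of a curated bacterial EF-P dataset so the
whole pipeline is testable without any downloads:

* a pure-birth (Yule) genome phylogeny,
* two correlated discrete characters evolving jointly on it — the residue at
  the loop tip (modification site, position 34 in E. coli numbering) and the
  residue two positions upstream (position 32, proline or not),
* KOW-like N-domain sequences carrying a seven-residue loop window (31-37)
  emitted from per-state profiles,
* paralog decoys (YeiP-annotated, same domain architecture) and
  wrong-architecture decoys,
* per-genome modification-enzyme repertoires (EpmA with lysine-type EF-P,
  EarP with arginine-type, with a configurable leak rate).

Defaults follow the composition of the published curated set: tip-residue
frequencies 81.11 % K, 14.75 % R, 0.51 % A, 0.77 % M, 2.23 % N, 0.6 % Q and
conditional proline co-occurrence 98.73 % (K), 2.33 % (R), 100 % (A, N),
0 % (M, Q).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm

__all__ = [
    "AMINO_ACIDS",
    "BACKBONE",
    "WINDOW_START",
    "WINDOW_END",
    "PairedCharacterModel",
    "SimulationConfig",
    "make_pair_model",
    "simulate_yule_tree",
    "simulate_paired_characters",
    "simulate_character",
    "emit_protein_set",
    "simulate_dataset",
    "SimulationResult",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# E. coli EF-P residues 1-65 (KOW-like N-domain); the loop window 31-37 is
# KPGKGQA with P32 at window position 2 and K34 at window position 4.
BACKBONE = (
    "MATYYSNDFRAGLKIMLDGEPYAVEASEFVKPGKGQAFARVKLRRLLTGTRVEKTFKSTDSAEGA"
)
WINDOW_START = 31  # 1-based, inclusive
WINDOW_END = 37

TIP_STATES = ("K", "R", "A", "M", "N", "Q")
MINUS2_STATES = ("P", "X")  # X = "not P"

# published composition of the curated set (fractions)
TIP_FREQS = {"K": 0.8111, "R": 0.1475, "A": 0.0051, "M": 0.0077, "N": 0.0223, "Q": 0.006}
P_GIVEN_TIP = {"K": 0.9873, "R": 0.0233, "A": 1.0, "M": 0.0, "N": 1.0, "Q": 0.0}

# consensus loop windows (E. coli 31-37 and the homologous P. putida window)
_K_CONSENSUS = "KPGKGQA"
_R_CONSENSUS = "KSGRNSA"

_TIP_IDX = 3  # 0-based index of the tip within the 7-residue window
_MINUS2_IDX = 1  # 0-based index of the -2 position


@dataclass(frozen=True)
class PairedCharacterModel:
    """Joint CTMC over (tip residue, minus-2 residue) product states.

    ``rate_matrix`` is indexed over the product space
    ``[(t, m) for t in tip_states for m in minus2_states]``.
    ``root_state`` is either one joint state or a probability vector over the
    joint space.
    """

    tip_states: tuple = TIP_STATES
    minus2_states: tuple = MINUS2_STATES
    rate_matrix: np.ndarray = None
    root_state: object = ("K", "P")

    @property
    def joint_states(self) -> list:
        return [(t, m) for t in self.tip_states for m in self.minus2_states]

    def state_index(self, state) -> int:
        return self.joint_states.index(tuple(state))

    def validate(self) -> None:
        k = len(self.tip_states) * len(self.minus2_states)
        q = np.asarray(self.rate_matrix, dtype=float)
        if q.shape != (k, k):
            raise ValueError(f"rate matrix must be {k}x{k}, got {q.shape}")
        off = q - np.diag(np.diag(q))
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be >= 0")
        if np.abs(q.sum(axis=1)).max() > 1e-12:
            raise ValueError("rate matrix rows must sum to 0")
        if not isinstance(self.root_state, tuple):
            p = np.asarray(self.root_state, dtype=float)
            if p.shape != (k,) or abs(p.sum() - 1) > 1e-9:
                raise ValueError("root_state distribution must sum to 1")


def make_pair_model(
    tip_freqs: dict = None,
    p_minus2_given_tip: dict = None,
    tip_rate: float = 0.7,
    minus2_relax_rate: float = 20.0,
    coupling: float = None,
    root_state=("K", "P"),
) -> PairedCharacterModel:
    """Build the default strongly coupled joint character model.

    The tip residue evolves by an F81-style chain with stationary frequencies
    ``tip_freqs`` and overall rate ``tip_rate``; conditional on the tip, the
    minus-2 position relaxes at rate ``minus2_relax_rate`` toward
    Bernoulli(``p_minus2_given_tip[tip]``) on {P, X}. A large relaxation rate
    makes the leaf-level minus-2 states nearly conditionally independent given
    the tips, with P(P | tip) equal to the configured conditional.

    ``coupling`` is a convenience: when given, it overrides
    P(P | K) = coupling and P(P | R) = 1 - coupling.
    """
    freqs = dict(TIP_FREQS if tip_freqs is None else tip_freqs)
    cond = dict(P_GIVEN_TIP if p_minus2_given_tip is None else p_minus2_given_tip)
    if coupling is not None:
        if not 0.0 <= coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        cond["K"] = coupling
        cond["R"] = 1.0 - coupling
    if tip_rate <= 0 or minus2_relax_rate <= 0:
        raise ValueError("rates must be positive")
    total = sum(freqs[t] for t in TIP_STATES)
    pi = np.array([freqs[t] / total for t in TIP_STATES])

    states = [(t, m) for t in TIP_STATES for m in MINUS2_STATES]
    k = len(states)
    q = np.zeros((k, k))
    for i, (ti, mi) in enumerate(states):
        for j, (tj, mj) in enumerate(states):
            if i == j:
                continue
            if mi == mj and ti != tj:
                # tip substitution, F81-style
                q[i, j] = tip_rate * pi[TIP_STATES.index(tj)]
            elif ti == tj and mi != mj:
                p = cond[ti]
                q[i, j] = minus2_relax_rate * (p if mj == "P" else 1.0 - p)
    np.fill_diagonal(q, -q.sum(axis=1))
    model = PairedCharacterModel(rate_matrix=q, root_state=root_state)
    model.validate()
    return model


def _default_profiles() -> dict:
    """Point-mass emission profiles per joint state (consensus windows)."""
    profiles = {}
    for tip in TIP_STATES:
        base = list(_R_CONSENSUS if tip == "R" else _K_CONSENSUS)
        base[_TIP_IDX] = tip
        for m2 in MINUS2_STATES:
            window = list(base)
            window[_MINUS2_IDX] = "P" if m2 == "P" else ("S" if base[_MINUS2_IDX] == "P" else base[_MINUS2_IDX])
            prof = np.zeros((7, len(AMINO_ACIDS)))
            for col, aa in enumerate(window):
                prof[col, AMINO_ACIDS.index(aa)] = 1.0
            profiles[(tip, m2)] = prof
    return profiles


@dataclass
class SimulationConfig:
    """All knobs of one synthetic dataset; defaults are the study conditions."""

    n_tips: int = 500
    birth_rate: float = 1.0
    pair_model: PairedCharacterModel = None
    loop_profiles: dict = None
    backbone_noise_rate: float = 0.02
    decoy_fraction: float = 0.2
    enzyme_leak: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.pair_model is None:
            self.pair_model = make_pair_model()
        if self.loop_profiles is None:
            self.loop_profiles = _default_profiles()
        self.validate()

    def validate(self) -> None:
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        for name in ("backbone_noise_rate", "enzyme_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must be in [0, 1)")
        self.pair_model.validate()
        for state, prof in self.loop_profiles.items():
            p = np.asarray(prof)
            if p.shape != (7, len(AMINO_ACIDS)):
                raise ValueError(f"profile for {state} must be 7x20")
            if np.abs(p.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError(f"profile columns for {state} must sum to 1")


def _stage_seeds(seed: int, n: int = 3):
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Simulate a pure-birth tree conditioned on ``n_tips`` extant lineages.

    Starting from the root bifurcation, each of the k extant lineages splits
    at rate ``birth_rate``; after the n-th tip appears one further exponential
    waiting time at rate ``n * birth_rate`` is added so that the expected root
    height is sum_{k=2..n} 1/(k*birth_rate). Leaves are labelled G0001... in
    order of creation; identical (n_tips, birth_rate, seed) triples give
    byte-identical Newick output.
    """
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    root = tree.seed_node
    root.edge.length = None
    if n_tips == 1:
        root.taxon = tns.new_taxon(label="G0001")
        return tree

    active = []
    for _ in range(2):
        child = dendropy.Node(edge_length=0.0)
        root.add_child(child)
        active.append(child)
    k = 2
    while k < n_tips:
        wait = float(rng.exponential(1.0 / (k * birth_rate)))
        for node in active:
            node.edge.length += wait
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node(edge_length=0.0)
            parent.add_child(child)
            active.append(child)
        k += 1
    wait = float(rng.exponential(1.0 / (k * birth_rate)))
    for node in active:
        node.edge.length += wait

    for i, leaf in enumerate(tree.leaf_nodes()):
        leaf.taxon = tns.new_taxon(label=f"G{i + 1:04d}")
    return tree


def _node_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


def simulate_paired_characters(
    tree: dendropy.Tree, model: PairedCharacterModel, seed: int
) -> dict:
    """Evolve the joint (tip, minus-2) character down a rooted tree.

    The root state is drawn from (or fixed to) ``model.root_state``; each
    child's state is drawn from the transition kernel expm(Q * branch length)
    of its parent's state. Internal nodes without labels are labelled
    N0001... in preorder. Returns {node label: (tip, minus2)} covering every
    node.
    """
    if not tree.is_rooted:
        raise ValueError("character simulation requires a rooted tree")
    model.validate()
    rng = np.random.default_rng(seed)
    q = np.asarray(model.rate_matrix, dtype=float)
    states = model.joint_states
    k = len(states)

    n_internal = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            n_internal += 1
            node.label = f"N{n_internal:04d}"
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("tree has a branch without a length")

    if isinstance(model.root_state, tuple):
        root_idx = model.state_index(model.root_state)
    else:
        root_idx = int(rng.choice(k, p=np.asarray(model.root_state, dtype=float)))

    kernels: dict = {}

    def kernel(t: float) -> np.ndarray:
        key = round(t, 15)
        if key not in kernels:
            p = expm(q * t)
            p = np.clip(p.real, 0.0, None)
            p /= p.sum(axis=1, keepdims=True)
            kernels[key] = p
        return kernels[key]

    assignment = {}
    idx_of = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            idx = root_idx
        else:
            p = kernel(float(node.edge.length))[idx_of[id(node.parent_node)]]
            idx = int(rng.choice(k, p=p))
        idx_of[id(node)] = idx
        assignment[_node_label(node)] = states[idx]
    return assignment


def simulate_character(tree: dendropy.Tree, rate_matrix, states, root_state, seed: int) -> dict:
    """Evolve one discrete character on a rooted tree (thin wrapper around
    :func:`simulate_paired_characters` with a singleton second character)."""
    model = PairedCharacterModel(
        tip_states=tuple(states),
        minus2_states=("*",),
        rate_matrix=np.asarray(rate_matrix, dtype=float),
        root_state=(root_state, "*") if isinstance(root_state, str) else root_state,
    )
    joint = simulate_paired_characters(tree, model, seed)
    return {label: s[0] for label, s in joint.items()}


def _mutate(seq: str, rate: float, rng, protect: set) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        if i in protect:
            continue
        alternatives = [a for a in AMINO_ACIDS if a != chars[i]]
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def _random_protein(rng, length: int) -> str:
    return "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, size=length))


_EFP_DOMAINS = ("EFP_N", "EFP", "Elong-fact-P_C")
_ENZYME_DOMAIN = {"epmA": "tRNA-synt_2", "epmC": "EpmC", "earP": "EarP", "dhs": "DS"}
_ENZYME_PRODUCT = {
    "epmA": "EF-P beta-lysine ligase EpmA",
    "epmC": "EF-P hydroxylase EpmC",
    "earP": "EF-P arginine rhamnosyltransferase EarP",
    "dhs": "deoxyhypusine synthase-like protein",
}
_DISTRACTOR_DOMAINS = ("HTH_1", "ABC_tran", "Response_reg")


def _true_evalue(rng) -> float:
    return float(10 ** rng.uniform(-60, -10))


def _weak_evalue(rng) -> float:
    return float(10 ** rng.uniform(-2, 0))


def emit_protein_set(tree: dendropy.Tree, states: dict, config: SimulationConfig):
    """Emit protein records, domain hits and genome annotations for one tree.

    Returns ``(records, hits, annotations, truth)`` where ``records`` is a
    list of :class:`~efp_loopscape.curation.ProteinRecord`, ``hits`` a list of
    :class:`~efp_loopscape.curation.DomainHit`, ``annotations`` a pandas
    DataFrame (genome_id, protein_id, product, epmA, epmC, earP, dhs) and
    ``truth`` a DataFrame flagging the planted EF-P records and decoy kinds.
    """
    import pandas as pd

    from .curation import DomainHit, ProteinRecord

    leaves = tree.leaf_nodes()
    for leaf in leaves:
        if leaf.taxon.label not in states:
            raise ValueError(f"leaf {leaf.taxon.label} has no simulated state")

    _, _, emit_seed = _stage_seeds(config.seed)
    rng = np.random.default_rng(emit_seed)

    window_lo, window_hi = WINDOW_START - 1, WINDOW_END  # 0-based half-open
    protect = set(range(window_lo, window_hi))

    records, hits, ann_rows, truth_rows = [], [], [], []

    def add_efp_hits(pid: str, domains, envelope_n=True):
        for d in domains:
            env = (1, 63) if (d == "EFP_N" and envelope_n) else None
            hits.append(DomainHit(protein_id=pid, domain_name=d, evalue=_true_evalue(rng), envelope=env))
        if rng.random() < 0.3:
            dom = _DISTRACTOR_DOMAINS[int(rng.integers(len(_DISTRACTOR_DOMAINS)))]
            hits.append(DomainHit(protein_id=pid, domain_name=dom, evalue=_weak_evalue(rng)))

    for leaf in leaves:
        genome = leaf.taxon.label
        tip, m2 = states[genome]
        prof = np.asarray(config.loop_profiles[(tip, m2)], dtype=float)
        window = [AMINO_ACIDS[int(rng.choice(20, p=prof[c]))] for c in range(7)]
        window[_TIP_IDX] = tip
        window[_MINUS2_IDX] = "P" if m2 == "P" else window[_MINUS2_IDX]
        if m2 != "P" and window[_MINUS2_IDX] == "P":
            window[_MINUS2_IDX] = "S"
        seq = BACKBONE[:window_lo] + "".join(window) + BACKBONE[window_hi:]
        seq = _mutate(seq, config.backbone_noise_rate, rng, protect)
        pid = f"{genome}_EFP"
        records.append(
            ProteinRecord(protein_id=pid, genome_id=genome, sequence=seq, product_annotation="elongation factor P")
        )
        add_efp_hits(pid, _EFP_DOMAINS)
        truth_rows.append({"protein_id": pid, "genome_id": genome, "is_efp": 1, "kind": "efp", "tip": tip, "minus2": m2})

        # modification-enzyme repertoire, with leak
        flags = {}
        flags["epmA"] = (tip == "K") != (rng.random() < config.enzyme_leak)
        flags["earP"] = (tip == "R") != (rng.random() < config.enzyme_leak)
        flags["epmC"] = bool(flags["epmA"] and rng.random() < 0.4)
        flags["dhs"] = bool(tip in ("K", "N") and rng.random() < 0.1)
        for enz, present in flags.items():
            if not present:
                continue
            epid = f"{genome}_{enz.upper()}"
            records.append(
                ProteinRecord(protein_id=epid, genome_id=genome, sequence=_random_protein(rng, 60), product_annotation=_ENZYME_PRODUCT[enz])
            )
            hits.append(DomainHit(protein_id=epid, domain_name=_ENZYME_DOMAIN[enz], evalue=_true_evalue(rng)))
            truth_rows.append({"protein_id": epid, "genome_id": genome, "is_efp": 0, "kind": f"enzyme_{enz}", "tip": tip, "minus2": m2})
        ann_rows.append({"genome_id": genome, "protein_id": pid, "product": "elongation factor P", **{k: int(v) for k, v in flags.items()}})

    n_decoys = int(round(config.decoy_fraction * len(leaves)))
    for d in range(n_decoys):
        genome = leaves[int(rng.integers(len(leaves)))].taxon.label
        pid = f"{genome}_DECOY{d + 1:04d}"
        seq = _mutate(BACKBONE, 0.1, rng, set())
        if d % 2 == 0:
            # YeiP paralog: same three-domain architecture, tell-tale annotation
            records.append(
                ProteinRecord(protein_id=pid, genome_id=genome, sequence=seq, product_annotation="elongation factor P-like protein YeiP")
            )
            add_efp_hits(pid, _EFP_DOMAINS)
            truth_rows.append({"protein_id": pid, "genome_id": genome, "is_efp": 0, "kind": "yeip", "tip": "", "minus2": ""})
        else:
            # wrong architecture: drop one domain or add a significant extra
            records.append(
                ProteinRecord(protein_id=pid, genome_id=genome, sequence=seq, product_annotation="hypothetical protein")
            )
            if rng.random() < 0.5:
                dropped = int(rng.integers(3))
                kept = [x for i, x in enumerate(_EFP_DOMAINS) if i != dropped]
                add_efp_hits(pid, kept, envelope_n=False)
            else:
                add_efp_hits(pid, _EFP_DOMAINS, envelope_n=False)
                extra = _DISTRACTOR_DOMAINS[int(rng.integers(len(_DISTRACTOR_DOMAINS)))]
                hits.append(DomainHit(protein_id=pid, domain_name=extra, evalue=_true_evalue(rng)))
            truth_rows.append({"protein_id": pid, "genome_id": genome, "is_efp": 0, "kind": "wrong_architecture", "tip": "", "minus2": ""})

    annotations = pd.DataFrame(ann_rows, columns=["genome_id", "protein_id", "product", "epmA", "epmC", "earP", "dhs"])
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "genome_id", "is_efp", "kind", "tip", "minus2"])
    return records, hits, annotations, truth


@dataclass
class SimulationResult:
    """One complete synthetic dataset plus its generating truth."""

    config: SimulationConfig
    tree: dendropy.Tree
    node_states: dict
    records: list
    hits: list
    annotations: object
    truth: object

    def leaf_states(self) -> dict:
        return {
            leaf.taxon.label: self.node_states[leaf.taxon.label]
            for leaf in self.tree.leaf_nodes()
        }

    def write(self, outdir) -> dict:
        """Write FASTA / TSV / Newick artifacts; returns the path map."""
        import os

        from . import curation
        from .trees import write_newick

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "proteins.fasta"),
            "hits": os.path.join(outdir, "domain_hits.tsv"),
            "domtblout": os.path.join(outdir, "domain_hits.domtblout"),
            "annotations": os.path.join(outdir, "genome_annotations.tsv"),
            "tree": os.path.join(outdir, "genomes.nwk"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "node_states": os.path.join(outdir, "node_states.tsv"),
        }
        curation.write_fasta(self.records, paths["fasta"])
        curation.write_hits_tsv(self.hits, paths["hits"])
        curation.write_domtblout(self.hits, paths["domtblout"])
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        write_newick(self.tree, paths["tree"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["node_states"], "w") as fh:
            fh.write("node\ttip\tminus2\n")
            for label in sorted(self.node_states):
                t, m = self.node_states[label]
                fh.write(f"{label}\t{t}\t{m}\n")
        return paths


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Run all generator stages from one root seed (per-stage child streams)."""
    tree_seed, char_seed, _ = _stage_seeds(config.seed)
    tree = simulate_yule_tree(config.n_tips, config.birth_rate, tree_seed)
    node_states = simulate_paired_characters(tree, config.pair_model, char_seed)
    records, hits, annotations, truth = emit_protein_set(tree, node_states, config)
    return SimulationResult(
        config=config,
        tree=tree,
        node_states=node_states,
        records=records,
        hits=hits,
        annotations=annotations,
        truth=truth,
    )
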