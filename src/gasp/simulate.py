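"""Synthetic data with known ground truth.

Two generators emulate the statistical structure the analysis pipeline
assumes, so every downstream operation can be validated against planted
truth:

* :func:`simulate_family` — a protease family evolving along a tree
  from a scaffold-derived root carrying a planted S1 triplet, catalytic
  triad and cysteine features.  Substitutions follow a uniform 20-state
  (Jukes–Cantor-like) jump process, position-uniform outside a set of
  *frozen* canonical sites (default: the full site registry), which
  keeps closed-form expectations available: for two leaves separated by
  expected ``d`` substitutions/site the per-mutable-site mismatch
  probability is ``(19/20)(1 - exp(-20 d / 19))``.  Optional short
  indels never overlap frozen sites (±3 residues), so planted-site
  recovery through the numbering module stays exact.

* :func:`simulate_locus` — a chromosome annotation in which protease
  genes sit between marker genes, subjected to duplication (adjacent
  copy), loss and strand-inversion events.  Gene sizes and intergap
  layout are a stylised deterministic function of gene index, so an
  event log fully determines the emitted annotation.

Every emitted artifact is reproducible: one master seed drives named
substreams (tree, sequences, locus events), and the event logs replay
to the exact outputs (:func:`replay_family`, :func:`replay_locus`).

:func:`make_fixture_suite` writes a small deterministic FASTA + GFF3 +
Newick + JSON fixture set covering every classifier rule, a broken
triad, a split locus, a marker inversion and a 6-taxon family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from gasp.classify import default_rules
from gasp.errors import InputError
from gasp.locus import GeneRecord, LocusDefinition, write_gff3
from gasp.numbering import AMINO_ACIDS, SITE_REGISTRY, ReferenceScaffold, default_scaffold
from gasp.phylogeny import write_newick

DEFAULT_FROZEN_LABELS = frozenset(SITE_REGISTRY.values())


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic-data generators.

    ``substitution_rate`` is expected substitutions per site per unit
    branch length; ``indel_rate`` is indel events per site per unit
    branch length; the locus event rates are per-locus probabilities
    per evolutionary step.  A fixed ``seed`` makes all outputs fully
    reproducible.
    """

    tree: dendropy.Tree | None = None
    n_leaves: int = 6
    mean_branch_length: float = 0.15
    substitution_rate: float = 1.0
    frozen_labels: frozenset[int] = DEFAULT_FROZEN_LABELS
    indel_rate: float = 0.0
    duplication_rate: float = 0.0
    loss_rate: float = 0.0
    inversion_rate: float = 0.0
    n_steps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "duplication_rate",
                     "loss_rate", "inversion_rate", "mean_branch_length"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        for prob in ("duplication_rate", "loss_rate", "inversion_rate"):
            if getattr(self, prob) > 1:
                raise InputError(f"{prob} is a per-step probability; must be <= 1")

    def streams(self) -> dict[str, np.random.Generator]:
        tree_ss, seq_ss, locus_ss = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "tree": np.random.default_rng(tree_ss),
            "sequence": np.random.default_rng(seq_ss),
            "locus": np.random.default_rng(locus_ss),
        }


# ---------------------------------------------------------------------------
# Sequence-family simulation


@dataclass
class SimulatedFamily:
    """A simulated protease family with full ground truth."""

    root_sequence: str
    tree: dendropy.Tree
    leaf_sequences: dict[str, str]
    events: list[dict]
    planted_triplet: str
    config: SimulationConfig = field(repr=False, default=None)


def _assign_sim_ids(tree: dendropy.Tree) -> None:
    """Stable node identifiers: leaf taxon labels; 'nodeK' preorder for internals."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.sim_id = node.taxon.label
        else:
            node.sim_id = f"node{k}"
            k += 1


def sample_tree(n_leaves: int, mean_branch_length: float, rng: np.random.Generator) -> dendropy.Tree:
    """Random topology by uniform pair joins, exponential branch lengths."""
    if n_leaves < 2:
        raise InputError("need >= 2 leaves")
    tns = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=tns)
    pool: list[dendropy.Node] = []
    for i in range(n_leaves):
        node = dendropy.Node()
        node.taxon = tns.get_taxon(f"t{i + 1}")
        pool.append(node)
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = dendropy.Node()
        for child in (pool[i], pool[j]):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(mean_branch_length))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    for child in pool:
        tree.seed_node.add_child(child)
        child.edge.length = float(rng.exponential(mean_branch_length))
    tree.is_rooted = False
    return tree


def make_root_sequence(
    scaffold: ReferenceScaffold | None = None,
    triplet: str = "DGG",
    triad_intact: bool = True,
    cys93: bool = False,
    bridge_191_220: bool = True,
) -> str:
    """Scaffold residues with the requested canonical-site features planted."""
    scaffold = scaffold or default_scaffold()
    if len(triplet) != 3 or any(c not in AMINO_ACIDS for c in triplet):
        raise InputError(f"triplet must be 3 canonical residues, got {triplet!r}")
    idx = scaffold.label_to_index
    seq = list(scaffold.residues)
    for lab, res in zip((189, 216, 226), triplet):
        seq[idx[lab]] = res
    for lab, res in zip((57, 102, 195), "HDS" if triad_intact else "HDA"):
        seq[idx[lab]] = res
    seq[idx[93]] = "C" if cys93 else "N"
    for lab in (191, 220):
        seq[idx[lab]] = "C" if bridge_191_220 else "S"
    return "".join(seq)


def _evolve_branch(
    seq: list[str],
    frozen: list[int],
    branch_id: str,
    length: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    events: list[dict],
) -> tuple[list[str], list[int]]:
    """Mutate one branch, appending replayable events; returns (seq, frozen)."""
    seq = list(seq)
    frozen = list(frozen)
    d = config.substitution_rate * length
    frozen_set = set(frozen)
    if d > 0:
        counts = rng.poisson(d, size=len(seq))
        for pos in range(len(seq)):
            if pos in frozen_set or counts[pos] == 0:
                continue
            for _ in range(int(counts[pos])):
                old = seq[pos]
                choices = [a for a in AMINO_ACIDS if a != old]
                new = choices[int(rng.integers(0, 19))]
                seq[pos] = new
                events.append(
                    {"type": "substitution", "branch": branch_id,
                     "position": pos, "from": old, "to": new}
                )
    n_indels = int(rng.poisson(config.indel_rate * length * len(seq))) if config.indel_rate else 0
    for _ in range(n_indels):
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        ilen = int(rng.integers(1, 4))
        guard = set()
        for f in frozen:
            guard.update(range(f - 3, f + 4))
        if kind == "deletion":
            valid = [
                p for p in range(len(seq) - ilen + 1)
                if not any(q in guard for q in range(p, p + ilen))
            ]
            if not valid:
                continue
            pos = valid[int(rng.integers(0, len(valid)))]
            removed = "".join(seq[pos : pos + ilen])
            del seq[pos : pos + ilen]
            frozen = [f - ilen if f >= pos + ilen else f for f in frozen]
            events.append(
                {"type": "deletion", "branch": branch_id, "position": pos, "residues": removed}
            )
        else:
            valid = [p for p in range(len(seq) + 1) if p not in guard]
            if not valid:
                continue
            pos = valid[int(rng.integers(0, len(valid)))]
            ins = "".join(AMINO_ACIDS[int(rng.integers(0, 20))] for _ in range(ilen))
            seq[pos:pos] = list(ins)
            frozen = [f + ilen if f >= pos else f for f in frozen]
            events.append(
                {"type": "insertion", "branch": branch_id, "position": pos, "residues": ins}
            )
        frozen_set = set(frozen)
    return seq, frozen


def simulate_family(
    config: SimulationConfig,
    scaffold: ReferenceScaffold | None = None,
    planted_triplet: str = "DGG",
    triad_intact: bool = True,
    cys93: bool = False,
    bridge_191_220: bool = True,
) -> SimulatedFamily:
    """Evolve a protease family along a tree from a planted root.

    The root is the bundled scaffold with the requested triplet, triad
    and cysteine features planted; frozen canonical sites (per the
    config) never mutate, so every descendant retains the planted
    profile.  The returned event log replays to the leaf sequences
    exactly (:func:`replay_family`).
    """
    scaffold = scaffold or default_scaffold()
    streams = config.streams()
    tree = config.tree
    if tree is None:
        tree = sample_tree(config.n_leaves, config.mean_branch_length, streams["tree"])
    _assign_sim_ids(tree)
    root_seq = make_root_sequence(
        scaffold, planted_triplet, triad_intact, cys93, bridge_191_220
    )
    idx = scaffold.label_to_index
    frozen0 = sorted(idx[lab] for lab in config.frozen_labels if lab in idx)

    rng = streams["sequence"]
    events: list[dict] = []
    leaf_sequences: dict[str, str] = {}
    state: dict[int, tuple[list[str], list[int]]] = {
        id(tree.seed_node): (list(root_seq), frozen0)
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq, parent_frozen = state[id(node.parent_node)]
        length = node.edge.length or 0.0
        seq, frozen = _evolve_branch(
            parent_seq, parent_frozen, node.sim_id, length, config, rng, events
        )
        state[id(node)] = (seq, frozen)
        if node.is_leaf():
            leaf_sequences[node.taxon.label] = "".join(seq)
    return SimulatedFamily(
        root_sequence=root_seq,
        tree=tree,
        leaf_sequences=leaf_sequences,
        events=events,
        planted_triplet=planted_triplet,
        config=config,
    )


def replay_family(
    root_sequence: str,
    tree: dendropy.Tree,
    events: list[dict],
) -> dict[str, str]:
    """Re-apply an event log to the root; returns the leaf sequences.

    Events are grouped per branch (preserving order) and applied along
    the tree's preorder traversal, exactly as the simulator emitted
    them.
    """
    if not all(hasattr(n, "sim_id") for n in tree.preorder_node_iter()):
        _assign_sim_ids(tree)
    per_branch: dict[str, list[dict]] = {}
    for ev in events:
        per_branch.setdefault(ev["branch"], []).append(ev)

    def apply(seq: list[str], evs: list[dict]) -> list[str]:
        seq = list(seq)
        for ev in evs:
            pos = ev["position"]
            if ev["type"] == "substitution":
                if seq[pos] != ev["from"]:
                    raise InputError(f"event log mismatch at {pos}: {seq[pos]} != {ev['from']}")
                seq[pos] = ev["to"]
            elif ev["type"] == "deletion":
                removed = "".join(seq[pos : pos + len(ev["residues"])])
                if removed != ev["residues"]:
                    raise InputError(f"deletion mismatch at {pos}")
                del seq[pos : pos + len(ev["residues"])]
            elif ev["type"] == "insertion":
                seq[pos:pos] = list(ev["residues"])
            else:
                raise InputError(f"unknown event type {ev['type']!r}")
        return seq

    leaves: dict[str, str] = {}
    state = {id(tree.seed_node): list(root_sequence)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        seq = apply(state[id(node.parent_node)], per_branch.get(node.sim_id, []))
        state[id(node)] = seq
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(seq)
    return leaves


def expected_mismatch_probability(d: float, n_states: int = 20) -> float:
    """Closed-form per-site mismatch probability of the uniform model.

    ``d`` is the expected number of substitutions per site along the
    path separating two sequences.
    """
    k = n_states
    return (k - 1) / k * (1.0 - np.exp(-k * d / (k - 1)))


# ---------------------------------------------------------------------------
# Locus simulation


@dataclass
class SimulatedLocus:
    """A simulated locus annotation plus its event log."""

    records: list[GeneRecord]
    events: list[dict]
    definition: LocusDefinition
    contig: str = "sim_contig"


def _seed_gene_names(definition: LocusDefinition, n_proteases: int) -> list[tuple[str, str]]:
    """Ordered (gene_id, category) pairs of the un-evolved locus."""
    names: list[tuple[str, str]] = []
    for m in definition.left_markers:
        names.append((m, "marker"))
    mid = [f"PROT{i + 1}" for i in range(n_proteases)]
    if definition.center_markers:
        half = len(mid) // 2
        for g in mid[:half]:
            names.append((g, "protease"))
        for m in definition.center_markers:
            names.append((m, "marker"))
        for g in mid[half:]:
            names.append((g, "protease"))
    else:
        for g in mid:
            names.append((g, "protease"))
    for m in definition.right_markers:
        names.append((m, "marker"))
    return names


def _layout(genes: list[tuple[str, str, str]], contig: str) -> list[GeneRecord]:
    """Deterministic stylised coordinates: size/gap are functions of index.

    ``genes`` holds (gene_id, category, strand) in locus order.  Sizes
    cycle through a few kb-scale values, gaps through tens of kb, so
    maps look genome-like while the event log alone fixes the output.
    """
    records = []
    pos = 1000
    for i, (gid, cat, strand) in enumerate(genes):
        size = 1500 + 700 * (i % 4)
        records.append(
            GeneRecord(gene_id=gid, contig=contig, start=pos, end=pos + size,
                       strand=strand, category=cat)
        )
        pos += size + 5000 + 2500 * (i % 3)
    return records


def simulate_locus(
    config: SimulationConfig,
    definition: LocusDefinition,
    n_proteases: int = 4,
    forced_events: list[dict] | None = None,
) -> SimulatedLocus:
    """Evolve a marker-delimited locus by duplication / loss / inversion.

    The seed locus is ``left markers | proteases | right markers`` (with
    centre markers, if any, between the proteases).  ``forced_events``
    are applied first, verbatim; then ``config.n_steps`` random steps
    fire each event type with its configured probability.  Duplication
    inserts an adjacent ``<gene>_dup`` copy, loss removes a protease,
    inversion flips a marker's strand.  Coordinates are recomputed from
    the stylised layout, so they stay sorted and non-negative, and
    :func:`replay_locus` reproduces the records from the event log
    alone.
    """
    rng = config.streams()["locus"]
    genes: list[tuple[str, str, str]] = [
        (gid, cat, "+") for gid, cat in _seed_gene_names(definition, n_proteases)
    ]
    events: list[dict] = list(forced_events or [])

    def apply_event(ev: dict) -> None:
        nonlocal genes
        kind = ev["type"]
        target = ev["target"]
        pos = next((i for i, g in enumerate(genes) if g[0] == target), None)
        if pos is None:
            raise InputError(f"event targets unknown gene {target!r}")
        if kind == "duplication":
            gid, cat, strand = genes[pos]
            copy_id = ev.get("copy_id", f"{gid}_dup")
            genes = genes[: pos + 1] + [(copy_id, cat, strand)] + genes[pos + 1 :]
        elif kind == "loss":
            genes = genes[:pos] + genes[pos + 1 :]
        elif kind == "inversion":
            gid, cat, strand = genes[pos]
            genes[pos] = (gid, cat, "-" if strand == "+" else "+")
        else:
            raise InputError(f"unknown locus event type {kind!r}")

    for ev in events:
        apply_event(ev)

    for _ in range(config.n_steps):
        proteases = [g for g in genes if g[1] == "protease"]
        markers = [g for g in genes if g[1] == "marker"]
        if config.duplication_rate and proteases and rng.random() < config.duplication_rate:
            target = proteases[int(rng.integers(0, len(proteases)))][0]
            n_copies = sum(1 for g in genes if g[0].startswith(f"{target}_dup")) + 1
            ev = {"type": "duplication", "target": target,
                  "copy_id": f"{target}_dup{n_copies}"}
            apply_event(ev)
            events.append(ev)
        proteases = [g for g in genes if g[1] == "protease"]
        if config.loss_rate and len(proteases) > 1 and rng.random() < config.loss_rate:
            ev = {"type": "loss", "target": proteases[int(rng.integers(0, len(proteases)))][0]}
            apply_event(ev)
            events.append(ev)
        if config.inversion_rate and markers and rng.random() < config.inversion_rate:
            ev = {"type": "inversion", "target": markers[int(rng.integers(0, len(markers)))][0]}
            apply_event(ev)
            events.append(ev)

    records = _layout(genes, "sim_contig")
    return SimulatedLocus(records=records, events=events, definition=definition)


def replay_locus(
    definition: LocusDefinition,
    n_proteases: int,
    events: list[dict],
) -> list[GeneRecord]:
    """Rebuild the simulated annotation from the event log alone."""
    sim = simulate_locus(
        SimulationConfig(n_steps=0), definition, n_proteases, forced_events=events
    )
    return sim.records


# ---------------------------------------------------------------------------
# Fixture suite


def make_fixture_suite(seed: int, outdir: str | Path) -> dict:
    """Write a deterministic fixture set; returns its manifest.

    Contents (all plain text, regenerated byte-identically per seed):

    * ``rules.fasta`` — one scaffold-derived sequence per literal
      classifier rule (planted triplet, intact triad);
    * ``triad_broken.fasta`` — an S195A azurocidin-like sequence;
    * ``family.fasta`` / ``family_true.nwk`` / ``family_events.json`` —
      a 6-taxon simulated family with planted DGG triplet;
    * ``locus.gff3`` / ``locus_events.json`` — a chymase-style locus
      with one duplication and one forced marker inversion;
    * ``locus_split.gff3`` — left and right markers on two contigs;
    * ``manifest.json`` — file list and planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rules = default_rules()
    scaffold = default_scaffold()

    rule_records = []
    for trip in sorted(rules.triplets):
        rule_records.append((f"rule_{trip}", make_root_sequence(scaffold, triplet=trip)))
    _write_fasta(rule_records, outdir / "rules.fasta")

    broken = make_root_sequence(scaffold, triplet="SGA", triad_intact=False)
    _write_fasta([("azurocidin_like", broken)], outdir / "triad_broken.fasta")

    fam_cfg = SimulationConfig(
        n_leaves=6, mean_branch_length=0.15, substitution_rate=1.0, seed=seed
    )
    family = simulate_family(fam_cfg, scaffold, planted_triplet="DGG")
    _write_fasta(sorted(family.leaf_sequences.items()), outdir / "family.fasta")
    write_newick(family.tree, outdir / "family_true.nwk")
    (outdir / "family_events.json").write_text(
        json.dumps(family.events, indent=0, sort_keys=True) + "\n"
    )

    chymase = LocusDefinition(
        name="chymase",
        left_markers=("RIPK3", "NYNRIN", "CBLN3", "SDR39U1"),
        right_markers=("STXBP6",),
    )
    forced = [
        {"type": "duplication", "target": "PROT2", "copy_id": "PROT2_dup1"},
        {"type": "inversion", "target": "STXBP6"},
    ]
    locus_sim = simulate_locus(
        SimulationConfig(seed=seed, n_steps=0), chymase, n_proteases=4, forced_events=forced
    )
    write_gff3(locus_sim.records, outdir / "locus.gff3")
    (outdir / "locus_events.json").write_text(
        json.dumps(locus_sim.events, indent=0, sort_keys=True) + "\n"
    )

    split_records = []
    left_part = _layout(
        [(m, "marker", "+") for m in chymase.left_markers]
        + [("PROTA", "protease", "+"), ("PROTB", "protease", "+")],
        "contigA",
    )
    right_part = _layout(
        [("PROTC", "protease", "+"), ("STXBP6", "marker", "+")], "contigB"
    )
    split_records = left_part + right_part
    write_gff3(split_records, outdir / "locus_split.gff3")

    manifest = {
        "seed": seed,
        "files": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
        "rule_triplets": sorted(rules.triplets),
        "family": {
            "planted_triplet": "DGG",
            "n_leaves": fam_cfg.n_leaves,
            "leaves": sorted(family.leaf_sequences),
        },
        "locus": {
            "inverted_markers": ["STXBP6"],
            "duplicated": ["PROT2"],
            "protease_genes": [
                g.gene_id for g in locus_sim.records if g.category == "protease"
            ],
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_fasta(records, path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
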