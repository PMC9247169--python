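"""Seeded synthetic study fixtures with known truth.

The generator emulates the statistical structure of a deep mito-nuclear
discordance study: two candidate resolutions of one internal branch related
by a single NNI, partitioned amino-acid alignments simulated on the "mt"
topology with per-marker signal strength, protein-coding nucleotide
sequences with a clade-specific G+T compositional excess, and a mock
annotated mitogenome whose unassigned regions carry the same clade bias.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import Alignment, write_fasta, write_map, write_partitions
from .likelihood import InvalidTreeError
from .models import SubstitutionModel, build_model
from .trees import leaf_labels, tree_from_string

#: amino acids whose codons carry G or T at both first and second positions
GT_RICH_RESIDUES = "FLVGCW"


class InvalidConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# topologies


@dataclass(frozen=True)
class TopologyPair:
    """Two resolutions of one deep branch, one NNI apart.

    ``tree_a`` groups the first two clades (the "mt-topology" analog);
    ``tree_b`` groups the first and third (the "nuc-topology" analog).
    """

    newick_a: str
    newick_b: str
    split_a: frozenset          # leaves grouped by the focal branch in tree_a
    split_b: frozenset
    clade_leaves: dict[str, tuple[str, ...]]

    @property
    def tree_a(self):
        return tree_from_string(self.newick_a)

    @property
    def tree_b(self):
        return tree_from_string(self.newick_b)


def _random_subtree(labels, rng, mean_length) -> str:
    """Random binary subtree over ``labels`` with exponential branch lengths."""
    items = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        right = items.pop(j)
        left = items.pop(i)
        la, lb = rng.exponential(mean_length, size=2)
        items.append(f"({left}:{la:.6f},{right}:{lb:.6f})")
    return items[0]


def make_topology_pair(
    leaf_labels_by_clade: dict[str, list[str]],
    seed: int,
    mean_branch_length: float = 0.1,
    focal_branch_length: float = 0.05,
) -> TopologyPair:
    """Build the NNI-related topology pair for ≥4 labeled clades.

    The first three clades play the roles of the discordant deep split: the
    focal branch groups clades 1+2 in ``tree_a`` and clades 1+3 in
    ``tree_b``; all other branch lengths and within-clade subtrees are
    shared, so the two trees differ by exactly one NNI (RF distance 2).
    """
    clades = {k: list(v) for k, v in leaf_labels_by_clade.items()}
    if len(clades) < 4:
        raise InvalidConfigurationError("need at least 4 clades")
    if any(len(v) < 1 for v in clades.values()):
        raise InvalidConfigurationError("every clade needs at least one leaf")
    n_total = sum(len(v) for v in clades.values())
    if n_total < 6:
        raise InvalidConfigurationError("need at least 6 leaves in total")
    rng = np.random.default_rng(seed)
    names = list(clades)
    sub = {c: _random_subtree(clades[c], rng, mean_branch_length) for c in names}
    attach = {c: rng.exponential(mean_branch_length) for c in names}
    c1, c2, c3 = names[:3]
    rest = names[3:]
    tail = ",".join(f"{sub[c]}:{attach[c]:.6f}" for c in rest)

    def build(inner_a, inner_b, outer):
        pair_part = (f"({sub[inner_a]}:{attach[inner_a]:.6f},"
                     f"{sub[inner_b]}:{attach[inner_b]:.6f})"
                     f":{focal_branch_length:.6f}")
        return f"({pair_part},{sub[outer]}:{attach[outer]:.6f},{tail});"

    newick_a = build(c1, c2, c3)
    newick_b = build(c1, c3, c2)
    return TopologyPair(
        newick_a=newick_a,
        newick_b=newick_b,
        split_a=frozenset(clades[c1] + clades[c2]),
        split_b=frozenset(clades[c1] + clades[c3]),
        clade_leaves={c: tuple(v) for c, v in clades.items()},
    )


# ---------------------------------------------------------------------------
# compositional shift


def apply_clade_shift(model: SubstitutionModel, shift_delta: float,
                      subset: str | None = None) -> SubstitutionModel:
    """Model with extra equilibrium mass on the G+T-associated states.

    For nucleotides the subset is ``GT``; for amino acids it is the
    GT-rich-codon residue set (``FLVGCW``).  Total mass of the subset grows
    by ``shift_delta`` and the remainder shrinks proportionally.
    """
    if shift_delta < 0:
        raise InvalidConfigurationError("shift_delta must be nonnegative")
    if subset is None:
        subset = "GT" if model.alphabet == "nt" else GT_RICH_RESIDUES
    mask = np.array([s in subset for s in model.states])
    pi = model.frequencies
    s = pi[mask].sum()
    if s + shift_delta >= 1.0:
        raise InvalidConfigurationError(
            "shift_delta pushes complementary frequencies below zero")
    if shift_delta == 0:
        return model.with_frequencies(pi)
    new = pi.copy()
    new[mask] *= (s + shift_delta) / s
    new[~mask] *= (1.0 - s - shift_delta) / (1.0 - s)
    return model.with_frequencies(new)


def shift_position_frequencies(pos_freqs: np.ndarray, shift_delta: float,
                               order: str = "ACGT") -> np.ndarray:
    """Apply the G+T shift to each row of a (3, 4) codon-position table."""
    mask = np.array([b in "GT" for b in order])
    out = np.asarray(pos_freqs, dtype=float).copy()
    for row in out:
        s = row[mask].sum()
        if s + shift_delta >= 1.0:
            raise InvalidConfigurationError("shift_delta too large for row")
        row[mask] *= (s + shift_delta) / s
        row[~mask] *= (1.0 - s - shift_delta) / (1.0 - s)
    return out


# ---------------------------------------------------------------------------
# sequence simulation


def _sample_rows(rng, probs_rows):
    """One categorical draw per row of ``probs_rows``."""
    u = rng.random(probs_rows.shape[0])
    return (u[:, None] < probs_rows.cumsum(axis=1)).argmax(axis=1)


def simulate_alignment(
    tree,
    model: SubstitutionModel,
    n_sites: int,
    seed,
    shift_leaves: set[str] | None = None,
    shift_model: SubstitutionModel | None = None,
) -> Alignment:
    """Evolve ``n_sites`` columns down ``tree`` under ``model``.

    Root states are drawn from the equilibrium frequencies; each site is
    assigned one discrete-gamma category and evolves with that category's
    mean rate on every branch.  Branches whose entire leaf set lies inside
    ``shift_leaves`` use ``shift_model`` instead (nonstationary composition
    shift on that clade's subtree).
    """
    if n_sites < 1:
        raise InvalidConfigurationError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    rates = model.category_rates
    k = len(rates)
    cat = rng.integers(0, k, size=n_sites)
    states: dict = {}
    root = tree.seed_node
    states[root] = rng.choice(model.n_states, size=n_sites, p=model.frequencies)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length
        if t is None:
            t = 0.0
        if t < 0:
            raise InvalidTreeError("negative branch length in simulation tree")
        m = model
        if shift_leaves is not None and shift_model is not None:
            below = {l.taxon.label for l in node.leaf_iter()}
            if below <= shift_leaves:
                m = shift_model
        parent = states[node.parent_node]
        child = np.empty(n_sites, dtype=np.int64)
        for c in range(k):
            mask = cat == c
            if not mask.any():
                continue
            p = m.transition_matrix(t, rates[c])
            child[mask] = _sample_rows(rng, p[parent[mask]])
        states[node] = child
    seqs = {}
    for leaf in tree.leaf_node_iter():
        seqs[leaf.taxon.label] = "".join(model.states[i] for i in states[leaf])
    return Alignment.from_sequences(seqs, alphabet=model.alphabet)


def simulate_cds(n_codons: int, position_frequencies, seed, code=None) -> str:
    """Independent codons from position-specific base frequencies, no stops."""
    from .composition import GeneticCode

    code = code or GeneticCode.from_table(5)
    pos = np.asarray(position_frequencies, dtype=float)
    if pos.shape != (3, 4):
        raise InvalidConfigurationError("position_frequencies must be (3, 4)")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    codons: list[str] = []
    while len(codons) < n_codons:
        need = n_codons - len(codons)
        cols = [bases[rng.choice(4, size=need, p=pos[i] / pos[i].sum())]
                for i in range(3)]
        draw = map("".join, zip(*cols))
        codons.extend(c for c in draw if c not in code.stop_codons)
    return "".join(codons[:n_codons])


# ---------------------------------------------------------------------------
# mock genome annotation


@dataclass(frozen=True)
class MockAnnotation:
    """Feature table over a mock mitogenome; 1-based inclusive coordinates."""

    genome_length: int
    features: tuple  # of (name, start, end, strand)

    def __post_init__(self):
        if self.genome_length < 1:
            raise InvalidConfigurationError("genome_length must be positive")
        for name, start, end, strand in self.features:
            if not (1 <= start <= end <= self.genome_length):
                raise InvalidConfigurationError(
                    f"feature {name!r} [{start}, {end}] outside genome bounds")

    def to_tsv(self, path):
        lines = ["name\tstart\tend\tstrand"]
        lines += [f"{n}\t{s}\t{e}\t{st}" for n, s, e, st in self.features]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path, genome_length):
        rows = []
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            n, s, e, st = line.split("\t")
            rows.append((n, int(s), int(e), st))
        return cls(genome_length, tuple(rows))


def default_mock_annotation(genome_length: int = 3000) -> MockAnnotation:
    """Gene blocks separated by unassigned gaps, covering ~85% of the genome."""
    features = []
    pos = 1
    names = ["cox1", "nadh2", "atp6", "cytb", "nadh5", "rrnL"]
    block = genome_length // (len(names) + 1)
    gap = block // 6
    for i, name in enumerate(names):
        start = pos + (gap if i else 0)
        end = min(start + block - gap - 1, genome_length)
        strand = "+" if i % 2 == 0 else "-"
        features.append((name, start, end, strand))
        pos = end + 1
    return MockAnnotation(genome_length, tuple(features))


# ---------------------------------------------------------------------------
# study configuration


@dataclass(frozen=True)
class PartitionSpec:
    """One marker: length, OXPHOS complex group, contact label, signal.

    ``signal`` scales the focal branch length for this marker's simulation;
    ``contact`` is ``mt`` for organellar markers, else ``contact`` /
    ``non-contact``; ``gene_tree`` picks which resolution the marker's gene
    tree shows.
    """

    name: str
    n_sites: int
    group: str
    contact: str = "mt"
    alphabet: str = "aa"
    signal: float = 1.0
    gene_tree: str = "mt"


def default_markers() -> list[PartitionSpec]:
    """Mitochondrial OXPHOS markers plus a nuclear contact/non-contact set.

    Mitochondrial lengths follow typical bivalve mitogenome protein sizes;
    the NADH markers are split into the minus-strand (nadh1,2,6) and
    plus-strand (nadh3,4,4l,5) groups.  Non-contact nuclear markers carry a
    tenfold weaker focal-branch signal than contact ones, mirroring the
    expectation that the discordant signal concentrates in subunits that
    physically touch the organellar ones.
    """
    mt = [
        ("atp6", 220, "CV"), ("atp8", 55, "CV"),
        ("cox1", 510, "CIV"), ("cox2", 220, "CIV"), ("cox3", 260, "CIV"),
        ("cytb", 370, "CIII"),
        ("nadh1", 310, "CI-ms"), ("nadh2", 320, "CI-ms"), ("nadh6", 160, "CI-ms"),
        ("nadh3", 115, "CI-ps"), ("nadh4", 440, "CI-ps"),
        ("nadh4l", 95, "CI-ps"), ("nadh5", 560, "CI-ps"),
    ]
    contact_names = {
        "CIV": ["cox4i1", "cox5a", "cox5b", "cox6a1", "cox6b1", "cox6c",
                "cox7a1", "cox7b", "cox7c", "cox8a"],
        "CIII": ["uqcrc1", "uqcrc2", "uqcrfs1", "uqcrb", "uqcrq",
                 "uqcr10", "uqcr11"],
        "CV": ["atp5f1a", "atp5f1b", "atp5f1c", "atp5f1d", "atp5f1e",
               "atp5mc1", "atp5me", "atp5mg"],
    }
    noncontact_names = {
        "CII": ["sdha", "sdhb", "sdhc", "sdhd"],
        "CIV": ["cox11", "cox15", "cox17", "cox19", "cox20", "sco1",
                "sco2", "surf1", "coa3", "coa6", "cmc1", "cmc2"],
        "CIII": ["bcs1l", "lyrm7", "uqcc1", "uqcc2", "uqcc3", "ttc19"],
        "CV": ["atp5pb", "atp5pd", "atp5pf", "atp5po", "atpaf1", "atpaf2",
               "atp5if1", "atp5md"],
    }
    contact = [(n, 200, g) for g, names in contact_names.items() for n in names]
    noncontact = [(n, 200, g) for g, names in noncontact_names.items()
                  for n in names]
    out = [PartitionSpec(n, s, g, "mt", signal=1.0) for n, s, g in mt]
    out += [PartitionSpec(n, s, g, "contact", signal=1.0) for n, s, g in contact]
    out += [PartitionSpec(n, s, g, "non-contact", signal=0.1, gene_tree="nuc")
            for n, s, g in noncontact]
    return out


#: codon-position base frequencies of an AT-skewed, GT-rich mitogenome
DEFAULT_POSITION_FREQUENCIES = np.array([
    [0.25, 0.15, 0.25, 0.35],   # position 1 (ACGT)
    [0.20, 0.20, 0.15, 0.45],   # position 2
    [0.30, 0.15, 0.15, 0.40],   # position 3
])


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study; all outputs derive from it."""

    clades: dict = field(default_factory=lambda: {
        "Heterodonta": 2, "Pteriomorphia": 2,
        "Palaeoheterodonta": 2, "Protobranchia": 2})
    partitions: tuple = field(default_factory=lambda: tuple(default_markers()))
    model_name: str = "poisson"
    alpha: float = 0.5
    n_categories: int = 4
    mean_branch_length: float = 0.1
    focal_branch_length: float = 0.05
    shift_clade: str = "Palaeoheterodonta"
    shift_delta: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if any(p.n_sites < 1 for p in self.partitions):
            raise InvalidConfigurationError("all partition lengths must be positive")
        if not (0 <= self.shift_delta < 0.5):
            raise InvalidConfigurationError("shift_delta must lie in [0, 0.5)")

    def leaf_labels_by_clade(self) -> dict[str, list[str]]:
        return {c: [f"{c}_{i + 1}" for i in range(n)]
                for c, n in self.clades.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["partitions"] = [dataclasses.asdict(p) for p in self.partitions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "partitions" in d:
            d["partitions"] = tuple(
                p if isinstance(p, PartitionSpec) else PartitionSpec(**p)
                for p in d["partitions"])
        return cls(**d)


@dataclass
class StudyFixture:
    """In-memory handle on a generated study, plus where it was written."""

    config: SimConfig
    pair: TopologyPair
    alignment: Alignment                  # concatenated, partitioned
    marker_alignments: dict[str, Alignment]
    cds: dict[str, dict[str, str]]        # marker -> taxon -> CDS
    genomes: dict[str, str]               # taxon -> genome sequence
    annotation: MockAnnotation
    taxon_clade: dict[str, str]
    marker_complex: dict[str, str]
    marker_contact: dict[str, str]
    gene_trees: dict[str, str]            # marker -> newick
    manifest: dict
    out_dir: Path | None = None


def _marker_rng_seed(seed: int, tag: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return np.random.SeedSequence(int.from_bytes(digest[:4], "big"))


def make_study_fixture(config: SimConfig, out_dir=None) -> StudyFixture:
    """Simulate the whole study and optionally write it to ``out_dir``.

    Every alignment evolves on the "mt" topology (``tree_a``); per-marker
    signal strength scales the focal branch.  The shifted clade's subtree
    uses a G+T-enriched model for both amino acids and nucleotides.
    """
    labels = config.leaf_labels_by_clade()
    pair = make_topology_pair(
        labels, config.seed,
        mean_branch_length=config.mean_branch_length,
        focal_branch_length=config.focal_branch_length)
    model = build_model(config.model_name, alpha=config.alpha,
                        n_categories=config.n_categories)
    shifted = apply_clade_shift(model, config.shift_delta)
    shift_leaves = set(labels[config.shift_clade])
    taxon_clade = {t: c for c, ts in labels.items() for t in ts}

    marker_alignments = {}
    gene_trees = {}
    for spec in config.partitions:
        focal = config.focal_branch_length * spec.signal
        marker_pair = make_topology_pair(
            labels, config.seed,
            mean_branch_length=config.mean_branch_length,
            focal_branch_length=focal)
        seed = _marker_rng_seed(config.seed, f"aln:{spec.name}")
        marker_alignments[spec.name] = simulate_alignment(
            marker_pair.tree_a, model, spec.n_sites, seed,
            shift_leaves=shift_leaves if config.shift_delta > 0 else None,
            shift_model=shifted if config.shift_delta > 0 else None)
        gene_trees[spec.name] = (pair.newick_a if spec.gene_tree == "mt"
                                 else pair.newick_b)
    alignment = Alignment.concatenate(marker_alignments)

    pos = DEFAULT_POSITION_FREQUENCIES
    pos_shifted = shift_position_frequencies(pos, config.shift_delta)
    cds: dict[str, dict[str, str]] = {}
    for spec in config.partitions:
        if spec.contact != "mt":
            continue
        per_taxon = {}
        for taxon in alignment.taxa:
            freqs = pos_shifted if taxon in shift_leaves else pos
            seed = _marker_rng_seed(config.seed, f"cds:{spec.name}:{taxon}")
            per_taxon[taxon] = simulate_cds(spec.n_sites, freqs, seed)
        cds[spec.name] = per_taxon

    annotation = default_mock_annotation()
    genomes = {}
    flat = pos.mean(axis=0)
    flat_shifted = pos_shifted.mean(axis=0)
    for taxon in alignment.taxa:
        freqs = flat_shifted if taxon in shift_leaves else flat
        rng = np.random.default_rng(_marker_rng_seed(config.seed, f"genome:{taxon}"))
        genomes[taxon] = "".join(
            np.array(list("ACGT"))[rng.choice(4, size=annotation.genome_length,
                                              p=freqs / freqs.sum())])

    marker_complex = {p.name: p.group for p in config.partitions}
    marker_contact = {p.name: p.contact for p in config.partitions}
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "truth": {
            "generating_topology": "mt",
            "focal_split_mt": sorted(pair.split_a),
            "focal_split_nuc": sorted(pair.split_b),
            "shift_clade": config.shift_clade,
            "shift_delta": config.shift_delta,
        },
        "tree_mt": pair.newick_a,
        "tree_nuc": pair.newick_b,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()

    fixture = StudyFixture(
        config=config, pair=pair, alignment=alignment,
        marker_alignments=marker_alignments, cds=cds, genomes=genomes,
        annotation=annotation, taxon_clade=taxon_clade,
        marker_complex=marker_complex, marker_contact=marker_contact,
        gene_trees=gene_trees, manifest=manifest,
        out_dir=Path(out_dir) if out_dir else None)
    if out_dir is not None:
        write_study_fixture(fixture, Path(out_dir))
    return fixture


def write_study_fixture(fx: StudyFixture, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    (out_dir / "markers").mkdir(parents=True, exist_ok=True)
    (out_dir / "cds").mkdir(exist_ok=True)
    (out_dir / "genomes").mkdir(exist_ok=True)
    for name, aln in fx.marker_alignments.items():
        write_fasta(aln, out_dir / "markers" / f"{name}.faa")
    write_fasta(fx.alignment, out_dir / "concatenated.faa")
    write_partitions(fx.alignment.partitions, out_dir / "partitions.txt")
    (out_dir / "tree_mt.nwk").write_text(fx.pair.newick_a + "\n")
    (out_dir / "tree_nuc.nwk").write_text(fx.pair.newick_b + "\n")
    for name, per_taxon in fx.cds.items():
        lines = []
        for taxon, seq in per_taxon.items():
            lines += [f">{taxon}", seq]
        (out_dir / "cds" / f"{name}.fna").write_text("\n".join(lines) + "\n")
    for taxon, seq in fx.genomes.items():
        (out_dir / "genomes" / f"{taxon}.fna").write_text(f">{taxon}\n{seq}\n")
    fx.annotation.to_tsv(out_dir / "annotation.tsv")
    write_map(fx.taxon_clade, out_dir / "taxon_clade.tsv", "taxon", "clade")
    write_map(fx.marker_complex, out_dir / "marker_complex.tsv", "marker", "complex")
    write_map(fx.marker_contact, out_dir / "marker_contact.tsv", "marker", "contact")
    with open(out_dir / "gene_trees.nwk", "w") as fh:
        for name in fx.gene_trees:
            fh.write(fx.gene_trees[name].strip() + "\n")
    (out_dir / "gene_tree_markers.txt").write_text(
        "\n".join(fx.gene_trees) + "\n")
    (out_dir / "manifest.json").write_text(
        json.dumps(fx.manifest, sort_keys=True, indent=1) + "\n")
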