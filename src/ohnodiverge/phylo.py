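"""Ohnologue-pair calling from gene trees plus Ss4R synteny.

A salmon Ss4R ohnologue pair is accepted when, on the rooted gene tree,

(i)   the two focal-species genes sit in a monophyletic clade containing
      only salmonid genes,
(ii)  the sister group of that clade is Northern pike,
(iii) at least one other salmonid species retains a mirrored pair, one
      gene in each duplicate sub-clade, and
(iv)  the two focal loci fall in the A/B intervals of one Ss4R collinear
      block (synteny support).

Each accepted pair is then dated by the mean windowed percent identity of
its block: >95 % late rediploidization, 90-95 % mid, <90 % early.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "GeneLeaf",
    "GeneTree",
    "TaxonGroups",
    "SyntenyMap",
    "OhnologPair",
    "parse_newick",
    "is_salmonid_only_clade",
    "sister_is_pike",
    "conserved_in_other_salmonid",
    "synteny_supported",
    "call_ohnolog_pairs",
    "classify_rediploidization",
    "chromosome_sort_key",
]


@dataclass(frozen=True)
class GeneLeaf:
    gene_id: str
    species_id: str
    chromosome: str
    start: int
    end: int

    @property
    def label(self) -> str:
        return f"{self.gene_id}|{self.species_id}|{self.chromosome}:{self.start}-{self.end}"


@dataclass
class GeneTree:
    """Rooted gene tree whose leaves carry (gene, species, locus)."""

    tree: dendropy.Tree
    orthogroup_id: str = ""
    leaves: dict[str, GeneLeaf] = field(default_factory=dict)

    def leaf_info(self, node: dendropy.Node) -> GeneLeaf:
        return self.leaves[node.taxon.label]

    def leaf_nodes_under(self, node: dendropy.Node) -> list[dendropy.Node]:
        return [lf for lf in node.leaf_iter()]

    def species_under(self, node: dendropy.Node) -> set[str]:
        return {self.leaf_info(lf).species_id for lf in node.leaf_iter()}

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class TaxonGroups:
    salmonids: set[str]
    pike: str
    outgroups: set[str]
    focal: str

    def __post_init__(self) -> None:
        if self.focal not in self.salmonids:
            raise ValueError("focal species must be a salmonid")
        if self.pike in self.salmonids or self.pike in self.outgroups:
            raise ValueError("species groups must be pairwise disjoint")
        if self.salmonids & self.outgroups:
            raise ValueError("species groups must be pairwise disjoint")

    @classmethod
    def from_table(cls, table: pd.DataFrame, focal: str) -> "TaxonGroups":
        by = table.groupby("group")["species"].apply(set).to_dict()
        pike = by.get("pike", set())
        if len(pike) != 1:
            raise ValueError("species-group table must name exactly one pike lineage")
        return cls(
            salmonids=set(by.get("salmonid", set())),
            pike=next(iter(pike)),
            outgroups=set(by.get("outgroup", set())),
            focal=focal,
        )


_LABEL_RE = re.compile(
    r"^(?P<gene>[^|]+)\|(?P<species>[^|]+)\|(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$"
)
# bare gene|species|chr:start-end tokens must be quoted before newick
# parsing, because the colon would otherwise read as a branch length
_BARE_LABEL_RE = re.compile(r"(?<![\w'])([^\s(),:;'\"]+\|[^\s(),:;'\"]+\|[^\s(),:;'\"]+:\d+-\d+)")


class NewickParseError(ValueError):
    pass


def _check_balanced(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(f"unbalanced '(' — {depth} unclosed at end of string")


def parse_newick(text: str, orthogroup_id: str = "") -> GeneTree:
    """Parse a rooted newick string with ``gene|species|chr:start-end`` leaves.

    Labels may be single-quoted or bare; bare labels are quoted
    internally so that their ``chr:start-end`` part is not mistaken for a
    branch length. Unrooted trees (``[&U]``) are rejected: rooting
    changes the sister-group criterion and must be explicit.
    """

    if "[&U]" in text:
        raise NewickParseError("unrooted tree rejected; provide a rooted topology")
    _check_balanced(text)
    quoted = _BARE_LABEL_RE.sub(r"'\1'", text)
    try:
        tree = dendropy.Tree.get(
            data=quoted, schema="newick", preserve_underscores=True, rooting="force-rooted"
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    leaves: dict[str, GeneLeaf] = {}
    for lf in tree.leaf_node_iter():
        if lf.taxon is None or not lf.taxon.label:
            raise NewickParseError("leaf without label")
        m = _LABEL_RE.match(lf.taxon.label)
        if not m:
            raise NewickParseError(
                f"leaf label {lf.taxon.label!r} does not match gene|species|chr:start-end"
            )
        info = GeneLeaf(
            gene_id=m["gene"],
            species_id=m["species"],
            chromosome=m["chrom"],
            start=int(m["start"]),
            end=int(m["end"]),
        )
        if info.gene_id in {v.gene_id for v in leaves.values()}:
            raise NewickParseError(f"duplicate gene id {info.gene_id!r} in tree")
        leaves[lf.taxon.label] = info
    return GeneTree(tree=tree, orthogroup_id=orthogroup_id, leaves=leaves)


# ---------------------------------------------------------------------------
# topology criteria
# ---------------------------------------------------------------------------

def is_salmonid_only_clade(gtree: GeneTree, node: dendropy.Node, groups: TaxonGroups) -> bool:
    """True iff every leaf below ``node`` belongs to a salmonid species."""

    return gtree.species_under(node) <= groups.salmonids


def sister_is_pike(
    gtree: GeneTree, clade_node: dendropy.Node, groups: TaxonGroups, mode: str = "exact"
) -> bool:
    """Check the sister group of ``clade_node`` against the pike lineage.

    ``mode='exact'`` (default) requires the sister leaf-species set to be
    exactly {pike}; ``mode='contains'`` relaxes to pike being present in
    the sister subtree.
    """

    parent = clade_node.parent_node
    if parent is None:
        raise ValueError("root node has no sister group")
    sister_species: set[str] = set()
    for sib in parent.child_nodes():
        if sib is not clade_node:
            sister_species |= gtree.species_under(sib)
    if mode == "exact":
        return sister_species == {groups.pike}
    if mode == "contains":
        return groups.pike in sister_species
    raise ValueError(f"unknown sister mode {mode!r}")


def conserved_in_other_salmonid(
    gtree: GeneTree, clade_node: dendropy.Node, groups: TaxonGroups, mode: str = "mirrored"
) -> bool:
    """Check that the duplication is retained in another salmonid.

    ``mode='mirrored'`` (default): some non-focal salmonid contributes at
    least one leaf to each of the two duplicate sub-clades (the children
    of ``clade_node``). ``mode='any2'`` relaxes to >=2 leaves anywhere in
    the clade.
    """

    others = groups.salmonids - {groups.focal}
    if mode == "any2":
        counts: dict[str, int] = {}
        for lf in clade_node.leaf_iter():
            sp = gtree.leaf_info(lf).species_id
            if sp in others:
                counts[sp] = counts.get(sp, 0) + 1
        return any(c >= 2 for c in counts.values())
    if mode != "mirrored":
        raise ValueError(f"unknown conservation mode {mode!r}")
    children = clade_node.child_nodes()
    if len(children) < 2:
        return False
    per_child = [
        {gtree.leaf_info(lf).species_id for lf in ch.leaf_iter()} & others for ch in children
    ]
    # species present in at least two different duplicate sub-clades
    for i in range(len(per_child)):
        for j in range(i + 1, len(per_child)):
            if per_child[i] & per_child[j]:
                return True
    return False


# ---------------------------------------------------------------------------
# synteny
# ---------------------------------------------------------------------------

@dataclass
class SyntenyMap:
    """Ss4R collinear blocks plus their 1-Mbp similarity windows."""

    blocks: pd.DataFrame  # block_id, chrA, startA, endA, chrB, startB, endB
    windows: pd.DataFrame  # block_id, window_index, pct_identity

    def __post_init__(self) -> None:
        b = self.blocks
        if len(b) and ((b.startA > b.endA) | (b.startB > b.endB)).any():
            raise ValueError("malformed block interval (start > end)")
        w = self.windows
        if len(w) and ((w.pct_identity < 0) | (w.pct_identity > 100)).any():
            raise ValueError("pct_identity must lie in [0, 100]")

    def mean_identity(self, block_id: str) -> float:
        sel = self.windows.loc[self.windows.block_id == block_id, "pct_identity"]
        return float(sel.mean()) if len(sel) else float("nan")


def _in_interval(chrom: str, start: int, end: int, c: str, s: int, e: int) -> bool:
    return chrom == c and start >= s and end <= e


def synteny_supported(
    locus1: tuple[str, int, int], locus2: tuple[str, int, int], synteny: SyntenyMap
) -> tuple[bool, str | None]:
    """True iff one locus sits in a block's A interval and the other in B.

    Either orientation counts; the first matching block (in table order)
    is reported.
    """

    for row in synteny.blocks.itertuples():
        a = (row.chrA, int(row.startA), int(row.endA))
        b = (row.chrB, int(row.startB), int(row.endB))
        if (_in_interval(*locus1, *a) and _in_interval(*locus2, *b)) or (
            _in_interval(*locus2, *a) and _in_interval(*locus1, *b)
        ):
            return True, str(row.block_id)
    return False, None


# ---------------------------------------------------------------------------
# classification & calling
# ---------------------------------------------------------------------------

DEFAULT_CLASS_BOUNDS = (90.0, 95.0)  # early < lo <= mid <= hi < late


def classify_rediploidization(
    window_identities, bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS
) -> str:
    """Date a pair's rediploidization era from windowed percent identity.

    Mean identity m -> 'late' if m > hi, 'mid' if lo <= m <= hi, 'early'
    if m < lo; 'unknown' when no windows are available.
    """

    vals = pd.Series(window_identities, dtype=float).dropna()
    if vals.empty:
        return "unknown"
    m = float(vals.mean())
    lo, hi = bounds
    if m > hi:
        return "late"
    if m >= lo:
        return "mid"
    return "early"


def chromosome_sort_key(chrom: str) -> tuple:
    """Numeric-aware ordering: 'ssa2' < 'ssa10', plain numbers sort numerically."""

    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class OhnologPair:
    gene1: str
    gene2: str
    orthogroup_id: str
    block_id: str
    mean_pct_identity: float
    rediploid_class: str


def _canonical_order(leaf_a: GeneLeaf, leaf_b: GeneLeaf) -> tuple[GeneLeaf, GeneLeaf]:
    ka = (chromosome_sort_key(leaf_a.chromosome), leaf_a.start, leaf_a.gene_id)
    kb = (chromosome_sort_key(leaf_b.chromosome), leaf_b.start, leaf_b.gene_id)
    return (leaf_a, leaf_b) if ka <= kb else (leaf_b, leaf_a)


def _candidate_clades(gtree: GeneTree, groups: TaxonGroups):
    """Maximal salmonid-only clades containing >=2 focal-species leaves."""

    for node in gtree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not is_salmonid_only_clade(gtree, node, groups):
            continue
        parent = node.parent_node
        if parent is not None and is_salmonid_only_clade(gtree, parent, groups):
            continue  # not maximal
        focal = [
            lf for lf in node.leaf_iter() if gtree.leaf_info(lf).species_id == groups.focal
        ]
        if len(focal) >= 2:
            yield node, focal


def call_ohnolog_pairs(
    trees,
    groups: TaxonGroups,
    synteny: SyntenyMap,
    sister_mode: str = "exact",
    conservation_mode: str = "mirrored",
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS,
) -> tuple[list[OhnologPair], list[str], list[dict]]:
    """Apply criteria (i)-(iii) plus synteny to every tree.

    Returns ``(pairs, singletons, ambiguous)``: accepted pairs in
    deterministic order (orthogroup id, then gene1 locus); focal genes
    from trees yielding no accepted pair as singletons; and clades with
    more than two focal genes (e.g. tandem duplicates inside the Ss4R
    clade), reported rather than resolved by guesswork. ``trees`` maps
    orthogroup id -> GeneTree or newick text.
    """

    import warnings

    pairs: list[OhnologPair] = []
    singletons: list[str] = []
    ambiguous: list[dict] = []
    for og in sorted(trees):
        gtree = trees[og]
        if isinstance(gtree, str):
            gtree = parse_newick(gtree, orthogroup_id=og)
        focal_leaves = [v for v in gtree.leaves.values() if v.species_id == groups.focal]
        if not focal_leaves:
            warnings.warn(f"tree {og}: no focal-species leaves, skipped")
            continue
        accepted: list[OhnologPair] = []
        for clade, focal_nodes in _candidate_clades(gtree, groups):
            if clade.parent_node is None:
                continue  # clade at root: no sister group to test
            if len(focal_nodes) > 2:
                ambiguous.append(
                    {
                        "orthogroup": og,
                        "genes": sorted(gtree.leaf_info(n).gene_id for n in focal_nodes),
                        "reason": ">2 focal genes in Ss4R clade",
                    }
                )
                continue
            if not sister_is_pike(gtree, clade, groups, mode=sister_mode):
                continue
            # the focal pair must split one per duplicate sub-clade
            children = clade.child_nodes()
            homes = []
            for n in focal_nodes:
                anc = n
                while anc.parent_node is not clade:
                    anc = anc.parent_node
                homes.append(anc)
            if len(set(id(h) for h in homes)) < 2:
                continue
            if not conserved_in_other_salmonid(gtree, clade, groups, mode=conservation_mode):
                continue
            la, lb = (gtree.leaf_info(n) for n in focal_nodes)
            ok, block_id = synteny_supported(
                (la.chromosome, la.start, la.end), (lb.chromosome, lb.start, lb.end), synteny
            )
            if not ok:
                continue
            g1, g2 = _canonical_order(la, lb)
            ident = synteny.mean_identity(block_id)
            accepted.append(
                OhnologPair(
                    gene1=g1.gene_id,
                    gene2=g2.gene_id,
                    orthogroup_id=og,
                    block_id=block_id,
                    mean_pct_identity=round(ident, 4),
                    rediploid_class=classify_rediploidization([ident], class_bounds),
                )
            )
        if accepted:
            pairs.extend(sorted(accepted, key=lambda p: (p.orthogroup_id, p.gene1)))
        else:
            paired_genes = {g for p in accepted for g in (p.gene1, p.gene2)}
            singletons.extend(
                sorted(v.gene_id for v in focal_leaves if v.gene_id not in paired_genes)
            )
    return pairs, singletons, ambiguous


def pairs_to_frame(pairs: list[OhnologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene1": p.gene1,
                "gene2": p.gene2,
                "orthogroup": p.orthogroup_id,
                "block": p.block_id,
                "mean_identity": p.mean_pct_identity,
                "class": p.rediploid_class,
            }
            for p in pairs
        ],
        columns=["gene1", "gene2", "orthogroup", "block", "mean_identity", "class"],
    )
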