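"""Data containers and readers/writers for the comparative NOGF analysis.

The pipeline relates the number of genes in each functional category (NOGF)
across mammalian species to body mass ``M`` [g] and mass-specific metabolic
rate ``B_c`` [W/g].  This module holds the core containers — the per-species
trait table, the species × category count matrix, the functional-category
hierarchy (third level nested in second level), and a rooted weighted
phylogeny — together with parsers for TSV, Newick, and KEGG BRITE flat
files, and the genus-representative filter used to thin phylogenetic
pseudo-replication before correlation analysis.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("petoscan")

__all__ = [
    "ValidationError",
    "NewickParseError",
    "KegFormatError",
    "SpeciesTable",
    "FunctionMatrix",
    "Hierarchy",
    "TreeNode",
    "PhyloTree",
    "parse_newick",
    "resolve_polytomies",
    "count_genes_per_category",
    "keg_hierarchy",
    "select_representatives",
]


class ValidationError(ValueError):
    """An input container violates one of its structural invariants."""


class NewickParseError(ValueError):
    """A Newick string is malformed; the message names the offending offset."""


class KegFormatError(ValueError):
    """A KEGG BRITE flat file violates the A/B/C/D block structure."""


# ---------------------------------------------------------------------------
# Species trait table
# ---------------------------------------------------------------------------

_REL_TOL = 1e-9


@dataclass
class SpeciesTable:
    """Per-species traits: body mass M [g] and mass-specific rate B_c [W/g].

    ``metabolic_rate_W`` (whole-organism B [W]) and ``genome_year`` are
    optional columns; when B is present it must satisfy B_c = B / M to a
    relative tolerance of 1e-9.
    """

    frame: pd.DataFrame

    REQUIRED = ("species_id", "genus", "body_mass_g", "mass_specific_rate_Wg")
    OPTIONAL = ("metabolic_rate_W", "genome_year")

    def __post_init__(self) -> None:
        f = self.frame.reset_index(drop=True).copy()
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise ValidationError(f"species table missing columns: {missing}")
        f["species_id"] = f["species_id"].astype(str)
        f["genus"] = f["genus"].astype(str)
        for col in ("body_mass_g", "mass_specific_rate_Wg", "metabolic_rate_W"):
            if col in f.columns:
                f[col] = pd.to_numeric(f[col], errors="raise")
        if "genome_year" in f.columns:
            f["genome_year"] = f["genome_year"].astype("Int64")

        dup = f["species_id"][f["species_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate species_id: {sorted(set(dup))}")
        for col in ("body_mass_g", "mass_specific_rate_Wg"):
            bad = f.loc[~(f[col] > 0), "species_id"].tolist()
            if bad:
                raise ValidationError(f"{col} must be > 0; offending species: {bad}")
        if "metabolic_rate_W" in f.columns:
            has_b = f["metabolic_rate_W"].notna()
            if has_b.any():
                sub = f[has_b]
                rel = (
                    (sub["mass_specific_rate_Wg"] - sub["metabolic_rate_W"] / sub["body_mass_g"]).abs()
                    / sub["mass_specific_rate_Wg"]
                )
                bad = sub.loc[rel >= _REL_TOL, "species_id"].tolist()
                if bad:
                    raise ValidationError(
                        f"mass_specific_rate_Wg inconsistent with metabolic_rate_W/body_mass_g for: {bad}"
                    )
        self.frame = f

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species_ids(self) -> list[str]:
        return self.frame["species_id"].tolist()

    @property
    def log10_mass(self) -> np.ndarray:
        """log10 body mass, aligned with :attr:`species_ids`."""
        return np.log10(self.frame["body_mass_g"].to_numpy(float))

    @property
    def log10_bc(self) -> np.ndarray:
        """log10 mass-specific metabolic rate, aligned with :attr:`species_ids`."""
        return np.log10(self.frame["mass_specific_rate_Wg"].to_numpy(float))

    def subset(self, species_ids: list[str]) -> "SpeciesTable":
        """Rows for ``species_ids``, in the given order."""
        idx = self.frame.set_index("species_id")
        missing = [s for s in species_ids if s not in idx.index]
        if missing:
            raise KeyError(f"species not in table: {missing}")
        sub = idx.loc[species_ids].reset_index()
        return SpeciesTable(sub)

    @classmethod
    def read_tsv(cls, path) -> "SpeciesTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# NOGF matrix
# ---------------------------------------------------------------------------


@dataclass
class FunctionMatrix:
    """Species × functional-category matrix of nonnegative gene counts (NOGF)."""

    species_ids: list[str]
    category_ids: list[str]
    counts: np.ndarray  # shape (n_species, n_categories), integer

    def __post_init__(self) -> None:
        self.species_ids = [str(s) for s in self.species_ids]
        self.category_ids = [str(c) for c in self.category_ids]
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(self.species_ids), len(self.category_ids)):
            raise ValidationError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.category_ids)} categories"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.all(np.isfinite(arr)) or np.any(arr != rounded):
                raise ValidationError("counts must be integers")
            arr = rounded.astype(np.int64)
        if np.any(arr < 0):
            raise ValidationError("counts must be nonnegative")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValidationError("duplicate species ids in matrix")
        if len(set(self.category_ids)) != len(self.category_ids):
            raise ValidationError("duplicate category ids in matrix")
        self.counts = np.ascontiguousarray(arr, dtype=np.int64)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_categories(self) -> int:
        return len(self.category_ids)

    def counts_for(self, category_id: str) -> np.ndarray:
        """Count vector (one entry per species) for one category, as floats."""
        j = self.category_ids.index(category_id)
        return self.counts[:, j].astype(float)

    def subset_species(self, species_ids: list[str]) -> "FunctionMatrix":
        pos = {s: i for i, s in enumerate(self.species_ids)}
        missing = [s for s in species_ids if s not in pos]
        if missing:
            raise KeyError(f"species not in matrix: {missing}")
        rows = [pos[s] for s in species_ids]
        return FunctionMatrix(list(species_ids), list(self.category_ids), self.counts[rows, :])

    @classmethod
    def read_tsv(cls, path, species_as_columns: bool = True) -> "FunctionMatrix":
        """Read a TSV matrix.

        The on-disk convention is categories as rows and species as columns
        (``species_as_columns=True``); pass ``False`` for the transposed
        layout.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        if species_as_columns:
            return cls(list(df.columns), list(df.index.astype(str)), df.to_numpy().T)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())

    def to_tsv(self, path, species_as_columns: bool = True) -> None:
        df = pd.DataFrame(self.counts.T, index=self.category_ids, columns=self.species_ids)
        df.index.name = "category_id"
        if not species_as_columns:
            df = df.T
            df.index.name = "species_id"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Functional hierarchy (third level -> second level)
# ---------------------------------------------------------------------------


@dataclass
class Hierarchy:
    """Mapping of third-level functional categories to their second-level parents."""

    mapping: dict[str, str]

    #: reserved parent for literature-curated gene sets (e.g. TSG/oncogene lists)
    CUSTOM = "custom"

    def upper_of(self, category_id: str) -> str:
        try:
            return self.mapping[category_id]
        except KeyError:
            raise KeyError(f"category not in hierarchy: {category_id!r}") from None

    def categories_in(self, upper_category_id: str) -> list[str]:
        return [c for c, u in self.mapping.items() if u == upper_category_id]

    @property
    def upper_categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self.mapping.values():
            seen.setdefault(u)
        return list(seen)

    def __contains__(self, category_id: str) -> bool:
        return category_id in self.mapping

    @classmethod
    def read_tsv(cls, path) -> "Hierarchy":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"category_id": list(self.mapping), "upper_category_id": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Rooted weighted phylogeny + Newick
# ---------------------------------------------------------------------------


class TreeNode:
    """A node of a rooted tree: leaf label, branch length to parent, children."""

    __slots__ = ("name", "branch_length", "children", "parent")

    def __init__(self, name=None, branch_length=None, children=None):
        self.name: str | None = name
        self.branch_length: float | None = branch_length
        self.children: list[TreeNode] = list(children) if children else []
        self.parent: TreeNode | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, bl={self.branch_length}, n_children={len(self.children)})"


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; tip names are species ids."""

    root: TreeNode

    def __post_init__(self) -> None:
        labels: list[str] = []
        for node in self.postorder():
            for child in node.children:
                child.parent = node
            if node.is_leaf():
                if node.name is None:
                    raise ValidationError("leaf without a label")
                labels.append(node.name)
            if node is not self.root:
                bl = node.branch_length
                if bl is None or not math.isfinite(bl) or bl < 0:
                    raise ValidationError(
                        f"non-root node {node.name!r} needs a finite branch length >= 0, got {bl}"
                    )
        self.root.parent = None
        dup = sorted({l for l in labels if labels.count(l) > 1})
        if dup:
            raise ValidationError(f"duplicate leaf labels: {dup}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[TreeNode]:
        """Children-before-parents node list (iterative; safe on deep trees)."""
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf()]

    @property
    def leaf_labels(self) -> list[str]:
        return [t.name for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf()]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                core = node.name
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    core += node.name
            if node.branch_length is not None:
                core += f":{node.branch_length!r}"
            return core

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        def dup(node: TreeNode) -> TreeNode:
            return TreeNode(node.name, node.branch_length, [dup(c) for c in node.children])

        return PhyloTree(dup(self.root))

    def prune_to(self, labels) -> "PhyloTree":
        """Subtree induced by ``labels``; unifurcations are collapsed by
        summing branch lengths."""
        keep = set(labels)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")

        def build(node: TreeNode) -> TreeNode | None:
            if node.is_leaf():
                return TreeNode(node.name, node.branch_length) if node.name in keep else None
            kids = [k for k in (build(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                only = kids[0]
                if node.branch_length is not None and only.branch_length is not None:
                    only.branch_length += node.branch_length
                elif node.branch_length is None:
                    only.branch_length = None if node.parent is None else only.branch_length
                return only
            return TreeNode(node.name, node.branch_length, kids)

        new_root = build(self.root)
        if new_root is None:
            raise ValidationError("pruning removed every tip")
        new_root.branch_length = None
        return PhyloTree(new_root)


class _NewickParser:
    """Recursive-descent parser for a single ';'-terminated Newick statement."""

    _LABEL_END = set("():,;[]\t\n ")

    def __init__(self, text: str):
        self.text = text
        self.i = 0
        self.seen_labels: dict[str, int] = {}

    def fail(self, msg: str, pos: int | None = None):
        pos = self.i if pos is None else pos
        raise NewickParseError(f"{msg} at offset {pos}")

    def peek(self) -> str:
        return self.text[self.i] if self.i < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.i < len(self.text) and self.text[self.i] in " \t\r\n":
            self.i += 1

    def parse(self) -> TreeNode:
        self.skip_ws()
        if not self.peek():
            self.fail("empty Newick input")
        root = self.parse_clade()
        self.skip_ws()
        if self.peek() != ";":
            self.fail("missing ';' terminator")
        self.i += 1
        self.skip_ws()
        if self.i != len(self.text):
            self.fail("trailing characters after ';'")
        return root

    def parse_clade(self) -> TreeNode:
        self.skip_ws()
        node = TreeNode()
        if self.peek() == "(":
            open_pos = self.i
            self.i += 1
            while True:
                node.children.append(self.parse_clade())
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.i += 1
                    continue
                if ch == ")":
                    self.i += 1
                    break
                self.fail("unbalanced parentheses", open_pos)
        self.skip_ws()
        start = self.i
        while self.peek() and self.peek() not in self._LABEL_END:
            self.i += 1
        label = self.text[start : self.i]
        if label:
            node.name = label
            if node.is_leaf():
                if label in self.seen_labels:
                    self.fail(f"duplicate leaf label {label!r}", start)
                self.seen_labels[label] = start
        self.skip_ws()
        if self.peek() == ":":
            self.i += 1
            self.skip_ws()
            num_start = self.i
            while self.peek() and self.peek() not in self._LABEL_END and self.peek() != "(":
                self.i += 1
            try:
                node.branch_length = float(self.text[num_start : self.i])
            except ValueError:
                self.fail("invalid branch length", num_start)
        return node


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick statement into a :class:`PhyloTree`.

    Raises :class:`NewickParseError` (naming the character offset) on
    unbalanced parentheses, duplicate leaf labels, or a missing ``;``.
    """
    return PhyloTree(_NewickParser(text).parse())


def resolve_polytomies(tree: PhyloTree, seed: int = 0) -> PhyloTree:
    """Arbitrarily resolve multifurcations into binary nodes with zero-length
    internal branches.  Opt-in preprocessing for the contrasts module, which
    rejects polytomies by default.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in out.postorder():
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            merged = TreeNode(None, 0.0, [a, b])
            merged.parent = node
            a.parent = merged
            b.parent = merged
            node.children = [c for k, c in enumerate(node.children) if k not in (i, j)]
            node.children.append(merged)
    return PhyloTree(out.root)


# ---------------------------------------------------------------------------
# KEGG BRITE flat files
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"<[^>]+>")


def _clean_label(text: str) -> str:
    """Strip HTML markup and surrounding whitespace from a BRITE label."""
    return _TAG_RE.sub("", text).strip()


def count_genes_per_category(keg_text: str) -> dict[str, int]:
    """Count genes per third-level (C) category of a KEGG BRITE flat file.

    Lines starting with ``A``/``B`` open higher hierarchy levels and close the
    current C block; ``D`` lines are gene entries belonging to the most recent
    C line.  Gene identifiers (the first whitespace token of a D line) are
    deduplicated within each category.  A ``D`` line before any ``C`` line is
    a format error.
    """
    genes: dict[str, set] = {}
    current: str | None = None
    for lineno, raw in enumerate(keg_text.splitlines(), start=1):
        if not raw.strip():
            continue
        prefix = raw[0]
        if prefix in ("A", "B"):
            current = None
        elif prefix == "C":
            label = _clean_label(raw[1:])
            current = label
            genes.setdefault(label, set())
        elif prefix == "D":
            if current is None:
                raise KegFormatError(f"line {lineno}: gene entry (D) before any category (C)")
            tokens = raw[1:].split()
            if tokens:
                genes[current].add(tokens[0])
        # other prefixes (#, !, %, +) are BRITE metadata; ignored
    return {cat: len(ids) for cat, ids in genes.items()}


def keg_hierarchy(keg_text: str) -> dict[str, str]:
    """Third-level (C) → second-level (B) parent mapping from a BRITE file.

    C lines before any B line map to the reserved parent ``"unclassified"``.
    """
    mapping: dict[str, str] = {}
    current_b: str | None = None
    for raw in keg_text.splitlines():
        if not raw.strip():
            continue
        if raw[0] == "B":
            label = _clean_label(raw[1:])
            if label:
                current_b = label
        elif raw[0] == "A":
            current_b = None
        elif raw[0] == "C":
            mapping[_clean_label(raw[1:])] = current_b or "unclassified"
    return mapping


# ---------------------------------------------------------------------------
# Genus-representative filter
# ---------------------------------------------------------------------------


def select_representatives(table: SpeciesTable, prefer: str = "earliest") -> SpeciesTable:
    """Keep one species per genus, chosen by genome completion year.

    ``prefer="earliest"`` (default) keeps the species whose genome was
    completed first; ``"latest"`` keeps the most recent.  Ties are broken
    lexicographically by species id.  A genus with several members but a
    missing ``genome_year`` is an error, since the choice would be undefined.
    """
    if prefer not in ("earliest", "latest"):
        raise ValueError(f"prefer must be 'earliest' or 'latest', got {prefer!r}")
    f = table.frame
    if "genome_year" not in f.columns:
        f = f.assign(genome_year=pd.Series([pd.NA] * len(f), dtype="Int64"))

    bad_genera = []
    keep_idx = []
    for genus, grp in f.groupby("genus", sort=False):
        if len(grp) == 1:
            keep_idx.append(grp.index[0])
            continue
        if grp["genome_year"].isna().any():
            bad_genera.append(genus)
            continue
        years = grp["genome_year"].astype(int)
        best = years.min() if prefer == "earliest" else years.max()
        tied = grp[years == best].sort_values("species_id")
        keep_idx.append(tied.index[0])
    if bad_genera:
        raise ValidationError(
            f"genome_year missing for multi-species genera: {sorted(bad_genera)}"
        )
    kept = f.loc[sorted(keep_idx)].reset_index(drop=True)
    n_dropped = len(f) - len(kept)
    if n_dropped:
        logger.info("select_representatives: dropped %d congeneric species", n_dropped)
    return SpeciesTable(kept)
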