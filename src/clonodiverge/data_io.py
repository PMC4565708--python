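"""Domain types and readers/writers for observation tables, character specs, matrices and trees.

The canonical observation format is a long CSV: one row per strain ×
individual × character × body side, with an integer state (a raw setal
count or a 0/1 presence state) or an empty value for a character that
could not be scored on that specimen.  Trees are exchanged as Newick
(parsed through dendropy) and binary taxon matrices additionally as
NEXUS ``DATATYPE=STANDARD``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "ThresholdRule",
    "CharacterSpec",
    "Observation",
    "ObservationTable",
    "TreeNode",
    "Tree",
    "BinaryTaxonMatrix",
    "read_observations",
    "write_observations",
    "read_specs",
    "write_specs",
    "read_tree",
    "write_tree",
    "write_nexus_matrix",
    "write_matrix_csv",
]

SIDES = ("left", "right", "none")
FAMILIES = ("binomial", "poisson")
BODY_PARTS = ("head", "thorax", "abdomen")


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class ThresholdRule:
    """Two-state grouping of an integer count character.

    Rare values and outliers are grouped with their nearest common value so
    the character can be analysed as a binomial variable.  With
    ``low_state_includes_cut`` (the default), values ``<= cut`` map to state
    0 and values ``> cut`` to state 1; otherwise ``>= cut`` maps to 1.
    The rule is total and monotone on the non-negative integers.
    """

    character_id: str
    cut: int
    low_state_includes_cut: bool = True

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values)
        if self.low_state_includes_cut:
            return (v > self.cut).astype(int)
        return (v >= self.cut).astype(int)


@dataclass(frozen=True)
class CharacterSpec:
    """Per-character metadata: model family, laterality, optional two-state rule.

    ``binarize_rule`` is present exactly for count characters whose
    distribution is nearly two-valued ("almost binomial") and that are
    analysed as binomial after outlier grouping.  Pure 0/1 characters and
    wide-range Poisson counts carry no rule.
    """

    character_id: str
    body_part: str
    family: str
    bilateral: bool = False
    binarize_rule: Optional[ThresholdRule] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r} for character {self.character_id}")
        if self.body_part not in BODY_PARTS:
            raise ValidationError(f"unknown body part {self.body_part!r} for character {self.character_id}")
        if self.binarize_rule is not None and self.family != "binomial":
            raise ValidationError(
                f"character {self.character_id}: a threshold rule implies a binomial analysis"
            )


@dataclass(frozen=True)
class Observation:
    strain_id: str
    individual_id: str
    character_id: str
    side: str = "none"
    value: Optional[int] = None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.missing == (self.value is not None):
            raise ValidationError("exactly one of value / missing must be set")
        if self.value is not None and self.value < 0:
            raise ValidationError("character states are non-negative integers")


class ObservationTable:
    """Long-format table of per-individual character observations.

    Wraps a pandas DataFrame with columns ``strain_id, individual_id,
    character_id, side, value`` (value NaN where missing) plus the
    character specifications used to validate it.
    """

    COLUMNS = ["strain_id", "individual_id", "character_id", "side", "value"]

    def __init__(self, df: pd.DataFrame, specs: Mapping[str, CharacterSpec]):
        df = df.loc[:, self.COLUMNS].copy()
        for c in ("strain_id", "individual_id", "character_id", "side"):
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        self.df = df.reset_index(drop=True)
        self.specs = dict(specs)
        self._validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_observations(
        cls, observations: Iterable[Observation], specs: Mapping[str, CharacterSpec]
    ) -> "ObservationTable":
        rows = [
            (o.strain_id, o.individual_id, o.character_id, o.side,
             np.nan if o.missing else float(o.value))
            for o in observations
        ]
        df = pd.DataFrame(rows, columns=cls.COLUMNS)
        return cls(df, specs)

    def _validate(self) -> None:
        unknown = set(self.df["character_id"]) - set(self.specs)
        if unknown:
            raise ValidationError(f"unknown character IDs: {sorted(unknown)}")
        bad_side = ~self.df["side"].isin(SIDES)
        if bad_side.any():
            raise ValidationError(
                f"invalid side value(s): {sorted(self.df.loc[bad_side, 'side'].unique())}"
            )
        for cid, sub in self.df.groupby("character_id", sort=False):
            spec = self.specs[cid]
            if spec.bilateral:
                if (sub["side"] == "none").any():
                    raise ValidationError(
                        f"character {cid} is bilateral; every observation needs side left/right"
                    )
            else:
                sided = sub["side"] != "none"
                if sided.any():
                    raise ValidationError(
                        f"character {cid} is not bilateral but has side-labelled observations"
                    )
        present = self.df["value"].notna()
        vals = self.df.loc[present, "value"]
        if (vals < 0).any() or (vals != np.round(vals)).any():
            raise ValidationError("character states must be non-negative integers")
        dup = self.df.duplicated(subset=["strain_id", "individual_id", "character_id", "side"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            r = self.df.iloc[i]
            raise ValidationError(
                "duplicate observation for "
                f"({r.strain_id}, {r.individual_id}, {r.character_id}, {r.side})"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def strains(self) -> list[str]:
        """Strain labels in order of first appearance."""
        return list(dict.fromkeys(self.df["strain_id"]))

    @property
    def characters(self) -> list[str]:
        return sorted(set(self.df["character_id"]))

    def __len__(self) -> int:
        return len(self.df)

    def values_by_strain(self, character_id: str, binarize: bool = True) -> dict[str, np.ndarray]:
        """Non-missing states per strain for one character (complete-case).

        Bilateral characters contribute one value per scored side.  When the
        character's spec carries a threshold rule and ``binarize`` is true,
        raw counts are grouped to 0/1 first.  Strains with no data for the
        character are omitted.
        """
        spec = self.specs[character_id]
        sub = self.df[(self.df["character_id"] == character_id) & self.df["value"].notna()]
        out: dict[str, np.ndarray] = {}
        for strain in self.strains:
            v = sub.loc[sub["strain_id"] == strain, "value"].to_numpy(dtype=float)
            if v.size == 0:
                continue
            v = v.astype(int)
            if binarize and spec.binarize_rule is not None:
                v = spec.binarize_rule.apply(v)
            out[strain] = v
        return out

    def cell_counts(self) -> pd.DataFrame:
        """Non-missing observation count per (strain, character) cell."""
        present = self.df[self.df["value"].notna()]
        return (
            present.pivot_table(index="strain_id", columns="character_id",
                                values="value", aggfunc="count")
            .fillna(0).astype(int)
        )

    def summary(self) -> pd.DataFrame:
        n_missing = self.df["value"].isna().groupby(self.df["character_id"]).sum()
        n_obs = self.df["value"].notna().groupby(self.df["character_id"]).sum()
        return pd.DataFrame({"n_obs": n_obs, "n_missing": n_missing}).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# observation / spec CSV I/O

_COLUMN_ALIASES = {
    "strain": "strain_id", "strain_id": "strain_id",
    "individual": "individual_id", "individual_id": "individual_id",
    "character": "character_id", "character_id": "character_id",
    "side": "side", "value": "value", "state": "value",
}


def read_observations(path, specs: Mapping[str, CharacterSpec] | Sequence[CharacterSpec]) -> ObservationTable:
    """Read a long-format observation CSV and validate it against the specs.

    Rows with an empty value field become missing observations.  Malformed
    values raise :class:`ParseError` naming the line; unknown character IDs
    or a side on a non-bilateral character raise :class:`ValidationError`.
    """
    if not isinstance(specs, Mapping):
        specs = {s.character_id: s for s in specs}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {}
    for c in raw.columns:
        key = c.strip().lower()
        if key in _COLUMN_ALIASES:
            cols[c] = _COLUMN_ALIASES[key]
    raw = raw.rename(columns=cols)
    needed = {"strain_id", "individual_id", "character_id", "value"}
    if not needed.issubset(raw.columns):
        raise ParseError(f"observation CSV must declare columns {sorted(needed)}")
    if "side" not in raw.columns:
        raw["side"] = "none"
    raw["side"] = raw["side"].replace({"": "none"}).str.strip().str.lower()
    values = np.full(len(raw), np.nan)
    for i, txt in enumerate(raw["value"]):
        txt = txt.strip()
        if txt == "" or txt.upper() in ("NA", "NAN"):
            continue
        try:
            values[i] = float(txt)
        except ValueError as exc:  # header is line 1
            raise ParseError(f"line {i + 2}: cannot parse value {txt!r}") from exc
    raw = raw.assign(value=values)
    return ObservationTable(raw, specs)


def write_observations(table: ObservationTable, path) -> None:
    out = table.df.copy()
    out["value"] = out["value"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def read_specs(path) -> dict[str, CharacterSpec]:
    """Read character specifications from CSV.

    Columns: character_id, body_part, family, bilateral, cut (empty for no
    threshold rule), low_state_includes_cut (optional), description.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    specs = {}
    for _, r in df.iterrows():
        cid = r["character_id"].strip()
        cut = r.get("cut", "").strip()
        rule = None
        if cut != "":
            inc = str(r.get("low_state_includes_cut", "true")).strip().lower() not in ("false", "0")
            rule = ThresholdRule(cid, int(cut), inc)
        specs[cid] = CharacterSpec(
            character_id=cid,
            body_part=r["body_part"].strip(),
            family=r["family"].strip(),
            bilateral=str(r.get("bilateral", "false")).strip().lower() in ("true", "1"),
            binarize_rule=rule,
            description=r.get("description", ""),
        )
    return specs


def write_specs(specs: Mapping[str, CharacterSpec], path) -> None:
    rows = []
    for cid in sorted(specs):
        s = specs[cid]
        rows.append({
            "character_id": s.character_id,
            "body_part": s.body_part,
            "family": s.family,
            "bilateral": s.bilateral,
            "cut": "" if s.binarize_rule is None else s.binarize_rule.cut,
            "low_state_includes_cut": (
                "" if s.binarize_rule is None else s.binarize_rule.low_state_includes_cut
            ),
            "description": s.description,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trees


class TreeNode:
    __slots__ = ("label", "children", "height")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[list["TreeNode"]] = None,
                 height: Optional[float] = None):
        self.label = label
        self.children = children if children is not None else []
        self.height = height

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leafset(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.label])
        out = set()
        for c in self.children:
            out |= c.leafset()
        return frozenset(out)

    def copy(self) -> "TreeNode":
        return TreeNode(self.label, [c.copy() for c in self.children], self.height)


class Tree:
    """Leaf-labelled tree, rooted or unrooted, with optional ultrametric heights.

    Unrooted trees are stored with an arbitrary (basal) node and compared by
    their nontrivial split sets; rooted trees by clade sets.  Heights, when
    present, are the merge heights of a dendrogram (leaves at height 0) and
    serialize as branch lengths (parent height minus child height).
    """

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        labels = []
        stack = [root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                labels.append(n.label)
            stack.extend(n.children)
        if len(labels) != len(set(labels)):
            raise ValidationError("leaf labels must be unique")
        self._leaves = frozenset(labels)

    # -- basics ------------------------------------------------------------
    @property
    def leaves(self) -> frozenset:
        return self._leaves

    def leaf_labels(self) -> list[str]:
        return sorted(self._leaves)

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), self.rooted)

    def clades(self, include_trivial: bool = False) -> frozenset:
        """Leafsets of internal nodes below the root (rooted comparison)."""
        out = set()

        def walk(n: TreeNode) -> frozenset:
            if n.is_leaf:
                ls = frozenset([n.label])
                if include_trivial:
                    out.add(ls)
                return ls
            ls = frozenset().union(*(walk(c) for c in n.children))
            if n is not self.root and len(ls) >= 2:
                out.add(ls)
            return ls

        walk(self.root)
        return frozenset(out)

    def splits(self) -> frozenset:
        """Canonical nontrivial bipartitions (unrooted comparison).

        Each split is the side that excludes the alphabetically smallest
        leaf, so split sets from differently rooted copies are comparable.
        """
        n = len(self._leaves)
        if n < 4:
            return frozenset()
        anchor = min(self._leaves)
        out = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            ls = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(ls) <= n - 2:
                side = ls if anchor not in ls else self._leaves - ls
                if 2 <= len(side) <= n - 2:
                    out.add(side)
            return ls

        walk(self.root)
        return frozenset(out)

    def heights(self) -> dict[frozenset, float]:
        """Merge height per internal clade (dendrograms)."""
        out: dict[frozenset, float] = {}

        def walk(n: TreeNode) -> frozenset:
            if n.is_leaf:
                return frozenset([n.label])
            ls = frozenset().union(*(walk(c) for c in n.children))
            if n.height is not None:
                out[ls] = n.height
            return ls

        walk(self.root)
        return out

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        has_heights = self.root.height is not None

        def fmt(n: TreeNode, parent_height: Optional[float]) -> str:
            if n.is_leaf:
                s = n.label
                h = 0.0
            else:
                s = "(" + ",".join(fmt(c, n.height) for c in n.children) + ")"
                h = n.height if n.height is not None else 0.0
            if has_heights and parent_height is not None:
                s += f":{parent_height - h:.10g}"
            return s

        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: bool = False) -> "Tree":
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
        lengths_ok = all(
            e.length is not None for e in dtree.preorder_edge_iter()
            if e.head_node is not dtree.seed_node
        )

        def conv(dn) -> tuple[TreeNode, float]:
            if dn.is_leaf():
                label = dn.taxon.label if dn.taxon is not None else dn.label
                return TreeNode(label=label), 0.0
            kids, depths = [], []
            for c in dn.child_nodes():
                node, d = conv(c)
                kids.append(node)
                depths.append(d + (c.edge.length or 0.0))
            h = max(depths) if lengths_ok else None
            return TreeNode(children=kids, height=h), (max(depths) if lengths_ok else 0.0)

        root, _ = conv(dtree.seed_node)
        return cls(root, rooted=rooted)


def write_tree(tree: Tree, path) -> str:
    """Serialize a tree to Newick; returns the text written."""
    text = tree.to_newick()
    with open(path, "w") as fh:
        fh.write(text + "\n")
    return text


def read_tree(path, rooted: bool = False) -> Tree:
    with open(path) as fh:
        return Tree.from_newick(fh.read(), rooted=rooted)


# ---------------------------------------------------------------------------
# binary taxon matrix


@dataclass
class BinaryTaxonMatrix:
    """Strains × characters 0/1 matrix for cladistic analysis.

    ``source_means`` keeps the scaled strain-mean matrix the states were
    derived from; ``uninformative`` lists constant columns (they add no
    parsimony signal but are retained in scoring).
    """

    taxa: list[str]
    characters: list[str]
    states: np.ndarray  # (n_taxa, n_char) of 0/1
    source_means: Optional[np.ndarray] = None
    uninformative: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValidationError("states shape does not match taxa × characters")
        if not np.isin(self.states, [0, 1]).all():
            raise ValidationError("states must be 0/1")

    def parsimony_informative(self) -> list[str]:
        """Characters with both states present in ≥2 taxa each."""
        out = []
        for j, cid in enumerate(self.characters):
            col = self.states[:, j]
            if (col == 0).sum() >= 2 and (col == 1).sum() >= 2:
                out.append(cid)
        return out


def write_nexus_matrix(matrix: BinaryTaxonMatrix, path) -> None:
    """Write the matrix as NEXUS DATA (DATATYPE=STANDARD, SYMBOLS="01")."""
    width = max(len(t) for t in matrix.taxa) + 2
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={len(matrix.characters)};\n")
    buf.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
    buf.write("    MATRIX\n")
    for i, t in enumerate(matrix.taxa):
        row = "".join(str(s) for s in matrix.states[i])
        buf.write(f"        {t:<{width}}{row}\n")
    buf.write("    ;\nEND;\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_matrix_csv(matrix: BinaryTaxonMatrix, path) -> None:
    pd.DataFrame(matrix.states, index=matrix.taxa, columns=matrix.characters).to_csv(
        path, index_label="strain_id"
    )


def read_matrix_csv(path) -> BinaryTaxonMatrix:
    df = pd.read_csv(path, index_col="strain_id")
    return BinaryTaxonMatrix(
        taxa=[str(t) for t in df.index],
        characters=[str(c) for c in df.columns],
        states=df.to_numpy(dtype=int),
    )
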