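"""Phylogenetic signal in T6SS effector presence/absence data.

Effectors are classified by molecular target as fast-lysing (peptidoglycan
amidases and glucosidases, phospholipases -- toxins that destroy the
structures maintaining cell integrity) or slow-lysing (DNases,
pore-formers, NAD(P)+ glycohydrolases).  For a clade ``c`` of ``N_c``
species and an effector ``e``, the within-clade similarity is the mean
pairwise agreement over all ordered species pairs, self-pairs included:

    S_ce = (1/N_c^2) * sum_ij delta_ij(e),   delta_ij = 1 if i and j both
    have, or both lack, e; else 0

which reduces to ``(k^2 + (N_c - k)^2) / N_c^2`` for ``k`` possessors.
Normalizing by the whole-tree similarity ``S_Tree,e`` gives a similarity
ratio whose decay across ascending taxon ranks (1 = subspecies ... 9 =
kingdom) indicates phylogenetic signal strength.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EffectorClass",
    "RANK_LEVELS",
    "classify_effector",
    "clade_similarity",
    "similarity_ratio_profile",
    "effector_summary",
    "AnnotatedTaxonomy",
    "SimilarityProfile",
    "UnclassifiedEffectorError",
]

RANK_LEVELS = {
    1: "subspecies", 2: "species", 3: "subgenus", 4: "genus", 5: "family",
    6: "order", 7: "class", 8: "phylum", 9: "kingdom",
}
_LEVEL_OF_RANK = {v: k for k, v in RANK_LEVELS.items()}


class EffectorClass:
    FAST = "FAST"
    SLOW = "SLOW"


class UnclassifiedEffectorError(KeyError):
    pass


# molecular-target catalog; aliases cover both target-style labels
# (Am-1..3, Mur, Glc, PLA1-2, PLD, ...) and gene-family names (Tae, Tge, Tle)
_FAST = {
    # peptidoglycan amidases
    "am-1": "peptidoglycan amidase", "am-2": "peptidoglycan amidase",
    "am-3": "peptidoglycan amidase",
    "tae1": "peptidoglycan amidase", "tae2": "peptidoglycan amidase",
    "tae3": "peptidoglycan amidase", "tae4": "peptidoglycan amidase",
    # peptidoglycan glucosidases
    "mur": "peptidoglycan glucosidase", "glc": "peptidoglycan glucosidase",
    "tge1": "peptidoglycan glucosidase", "tge2": "peptidoglycan glucosidase",
    "tge3": "peptidoglycan glucosidase",
    # phospholipases
    "pla1": "phospholipase", "pla2": "phospholipase", "pld": "phospholipase",
    "tle1": "phospholipase", "tle2": "phospholipase", "tle3": "phospholipase",
    "tle4": "phospholipase", "tle5": "phospholipase",
}
_SLOW = {
    "tox43": "DNase", "tox34": "DNase",
    "tse4": "pore-forming", "vasx": "pore-forming",
    "tox46": "NAD(P)+ glycohydrolase",
}


def classify_effector(label: str) -> str:
    """FAST or SLOW for a known effector label; unknown labels raise."""
    key = str(label).strip().lower()
    if key in _FAST:
        return EffectorClass.FAST
    if key in _SLOW:
        return EffectorClass.SLOW
    raise UnclassifiedEffectorError(
        f"effector {label!r} is not in the fast/slow catalog")


def effector_target(label: str) -> str:
    key = str(label).strip().lower()
    return {**_FAST, **_SLOW}[key]


def clade_similarity(clade_species, effector: str, presence) -> float:
    """S_ce for one clade: ordered-pair agreement including self-pairs.

    ``presence`` maps species -> set of effectors (or is a bool DataFrame
    species x effector).  Always lies in [0.5, 1]; the lower bound is
    attained exactly at an even split with even N_c.
    """
    species = list(clade_species)
    n = len(species)
    if n == 0:
        raise ValueError("empty clade")
    if isinstance(presence, pd.DataFrame):
        k = int(presence.loc[species, effector].sum()) if effector in presence.columns else 0
    else:
        k = sum(1 for s in species if effector in presence.get(s, ()))
    return (k * k + (n - k) * (n - k)) / (n * n)


@dataclass
class SimilarityProfile:
    effector: str
    tree_similarity: float                       # S_Tree,e
    ratios: dict[int, np.ndarray] = field(default_factory=dict)  # level -> per-clade S_ce/S_Tree,e
    means: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.effector, lvl, RANK_LEVELS[lvl], r, self.means[lvl])
                for lvl in sorted(self.ratios)
                for r in self.ratios[lvl]]
        return pd.DataFrame(rows, columns=["effector", "level", "rank",
                                           "similarity_ratio", "level_mean"])


class AnnotatedTaxonomy:
    """Ranked species taxonomy with per-species effector presence sets.

    ``levels[l]`` assigns each species a clade label at rank level ``l``
    (1 = subspecies ... 9 = kingdom); missing intermediate ranks collapse
    to the nearest present ancestor so every species has a full path.
    """

    def __init__(self, species: list[str], levels: dict[int, list],
                 presence: dict[str, set], catalog: dict[str, str] | None = None):
        self.species = list(species)
        n = len(self.species)
        self.levels: dict[int, np.ndarray] = {}
        filled = ["__root__"] * n
        for lvl in range(9, 0, -1):  # collapse missing ranks upward to ancestors
            labels = levels.get(lvl)
            if labels is not None and len(labels) != n:
                raise ValueError(f"level {lvl}: wrong label count")
            if labels is None:
                labels = [None] * n
            # nest labels under the parent so same-named clades in different
            # branches never merge; missing labels collapse to the parent
            filled = [prev if x is None or str(x) in ("", "nan")
                      else f"{prev}/{x}"
                      for x, prev in zip(labels, filled)]
            self.levels[lvl] = np.array(filled, dtype=object)
        # level 1 defaults to singleton subspecies if absent
        if levels.get(1) is None:
            self.levels[1] = np.array(
                [f"{p}/{s}" for p, s in zip(self.levels[2], self.species)],
                dtype=object)
        self.presence = {s: set(presence.get(s, set())) for s in self.species}
        self.effectors = sorted({e for s in self.presence.values() for e in s})
        if catalog is None:
            catalog = {}
            for e in self.effectors:
                catalog[e] = classify_effector(e)
        self.catalog = catalog

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_rank_table(cls, ranks: pd.DataFrame | str | Path,
                        presence: pd.DataFrame | str | Path) -> "AnnotatedTaxonomy":
        """Build from a TSV rank table (species + rank-name columns) and a
        tidy effector presence TSV (columns: species, effector[, present])."""
        if not isinstance(ranks, pd.DataFrame):
            ranks = pd.read_csv(ranks, sep="\t", dtype=str)
        pres = _load_presence(presence)
        species = ranks["species"].astype(str).tolist()
        levels = {}
        for col in ranks.columns:
            if col == "species":
                levels[2] = species
                continue
            lvl = _LEVEL_OF_RANK.get(col.lower())
            if lvl is None:
                raise ValueError(f"unknown rank column {col!r}")
            levels[lvl] = ranks[col].tolist()
        return cls(species, levels, pres)

    @classmethod
    def from_newick(cls, source: str | Path,
                    presence: pd.DataFrame | str | Path | dict) -> "AnnotatedTaxonomy":
        """Build from a Newick taxonomy whose internal-node labels carry rank
        annotations of the form ``'rank=name'`` (quoted, e.g.
        ``'genus=Vibrio'``); unannotated internals are treated as unnamed
        intermediate levels.  Leaf labels are the species names.
        """
        import dendropy

        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        tree = dendropy.Tree.get(data=text, schema="newick")
        pres = presence if isinstance(presence, dict) else _load_presence(presence)
        species = [lf.taxon.label for lf in tree.leaf_node_iter()]
        levels: dict[int, list] = {lvl: [None] * len(species) for lvl in range(3, 10)}
        index = {s: k for k, s in enumerate(species)}
        for node in tree.preorder_node_iter():
            label = node.label if not node.is_leaf() else None
            if not label or "=" not in str(label):
                continue
            rank, name = str(label).split("=", 1)
            lvl = _LEVEL_OF_RANK.get(rank.strip().lower())
            if lvl is None:
                continue
            for lf in node.leaf_iter():
                levels[lvl][index[lf.taxon.label]] = name.strip()
        # the root always closes the hierarchy at the kingdom level
        levels[9] = ["__root__"] * len(species)
        return cls(species, {2: species, **levels}, pres)

    # -- queries -------------------------------------------------------------

    def clades(self, level: int) -> list[np.ndarray]:
        """Species-index arrays of the maximal clades at a rank level."""
        labels = self.levels[level]
        return [np.flatnonzero(labels == lab) for lab in pd.unique(labels)]

    def to_newick(self, annotate_effectors: bool = True) -> str:
        """Annotated Newick export: internal labels ``'rank=name'``, leaf
        comments carrying the effector presence set."""
        def subtree(indices, level):
            if level < 3:  # species level: emit leaves
                parts = []
                for k in indices:
                    leaf = self.species[k]
                    if annotate_effectors and self.presence[leaf]:
                        leaf += "[&effectors=%s]" % "|".join(
                            sorted(self.presence[leaf]))
                    parts.append(leaf)
                return ",".join(parts)
            labels = self.levels[level]
            groups: dict[str, list[int]] = {}
            for k in indices:
                groups.setdefault(labels[k], []).append(k)
            parts = []
            for label, idxs in groups.items():
                inner = subtree(idxs, level - 1)
                name = label.rsplit("/", 1)[-1]
                parts.append(f"({inner})'{RANK_LEVELS[level]}={name}'"
                             if len(idxs) > 1 else inner)
            return ",".join(parts)

        return "(%s)'kingdom=root';" % subtree(list(range(len(self.species))), 8)

    def possession_counts(self, effector: str) -> np.ndarray:
        return np.array([1 if effector in self.presence[s] else 0
                         for s in self.species])

    def tree_similarity(self, effector: str) -> float:
        return clade_similarity(self.species, effector, self.presence)


def similarity_ratio_profile(taxonomy: AnnotatedTaxonomy,
                             effector: str) -> SimilarityProfile:
    """Per-level clade similarity ratios S_ce / S_Tree,e for one effector.

    At level 9 there is a single clade (the whole tree) and the ratio is 1
    by construction.
    """
    s_tree = taxonomy.tree_similarity(effector)
    prof = SimilarityProfile(effector=effector, tree_similarity=s_tree)
    have = taxonomy.possession_counts(effector)
    for lvl in range(1, 10):
        vals = []
        for clade in taxonomy.clades(lvl):
            n = len(clade)
            k = int(have[clade].sum())
            vals.append(((k * k + (n - k) * (n - k)) / (n * n)) / s_tree)
        prof.ratios[lvl] = np.array(vals)
        prof.means[lvl] = float(np.mean(vals))
    return prof


def _load_presence(presence) -> dict[str, set]:
    if isinstance(presence, dict):
        return presence
    if not isinstance(presence, pd.DataFrame):
        presence = pd.read_csv(presence, sep="\t", dtype=str)
    df = presence
    if "effector" in df.columns:  # tidy: species, effector[, present]
        if "present" in df.columns:
            df = df[df["present"].astype(str).str.lower().isin(["1", "true", "yes"])]
        out: dict[str, set] = {}
        for sp, eff in zip(df["species"], df["effector"]):
            out.setdefault(str(sp), set()).add(str(eff))
        return out
    # wide boolean table indexed by species
    wide = df.set_index("species") if "species" in df.columns else df
    return {str(sp): {c for c in wide.columns if bool(int(wide.loc[sp, c]))}
            for sp in wide.index}


def effector_summary(presence) -> dict:
    """Dataset-level counts: total effector occurrences, fast-lysing count
    and fraction, and the number/fraction of strains carrying >= 1
    fast-lysing effector.  Every effector must be classifiable."""
    pres = _load_presence(presence)
    if not pres or all(len(v) == 0 for v in pres.values()):
        raise ValueError("empty effector table")
    total = 0
    fast = 0
    strains_with_fast = 0
    for effectors in pres.values():
        has_fast = False
        for e in effectors:
            total += 1
            if classify_effector(e) == EffectorClass.FAST:
                fast += 1
                has_fast = True
        strains_with_fast += int(has_fast)
    n_strains = len(pres)
    return {
        "n_effectors": total,
        "n_fast": fast,
        "fraction_fast": fast / total,
        "n_strains": n_strains,
        "n_strains_with_fast": strains_with_fast,
        "fraction_strains_with_fast": strains_with_fast / n_strains,
    }
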