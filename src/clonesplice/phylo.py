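"""Clone phylogenies from binary colony x variant matrices, and
molecular-clock dating of driver acquisition.

The reconstruction assumes a perfect phylogeny: every somatic variant arises
once and never reverts, so variant carrier-sets must be pairwise nested or
disjoint (the three-gamete condition).  Dating assumes clock-like mutation
accrual: colony mutation burdens grow as Poisson(rate x age), so mutation
counts along the trunk bound, in molecular time, when a driver was acquired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CloneSpliceError, IncompatibleMatrixError, InputError

__all__ = [
    "BinaryMutationMatrix",
    "CloneNode",
    "CloneTree",
    "ColonyClusters",
    "MutationRateEstimate",
    "AgeInterval",
    "cluster_colonies",
    "build_clone_tree",
    "estimate_mutation_rate",
    "date_acquisition",
]


@dataclass
class BinaryMutationMatrix:
    """Colonies x variants 0/1 matrix with optional per-colony metadata.

    Entries may be NaN (missing genotype); missing entries are excluded
    from carrier sets rather than treated as absent, since colony dropout
    is technical.
    """

    matrix: pd.DataFrame
    compartment: pd.Series | None = None
    age_years: pd.Series | None = None

    def __post_init__(self):
        if self.matrix.columns.duplicated().any():
            raise InputError("variant ids must be unique")
        if self.matrix.index.duplicated().any():
            raise InputError("colony ids must be unique")
        if len(self.matrix) and self.matrix.isna().all(axis=1).any():
            bad = self.matrix.index[self.matrix.isna().all(axis=1)][0]
            raise InputError(f"colony {bad!r} has no observed genotype calls")
        vals = self.matrix.to_numpy()
        ok = (vals == 0) | (vals == 1)
        if np.issubdtype(vals.dtype, np.floating):
            ok |= np.isnan(vals)
        if not ok.all():
            raise InputError("matrix entries must be 0, 1 or missing")

    @property
    def colonies(self):
        return list(self.matrix.index)

    @property
    def variants(self):
        return list(self.matrix.columns)

    def carriers(self, variant: str) -> frozenset:
        col = self.matrix[variant]
        return frozenset(col.index[col == 1])

    def variant_set(self, colony: str) -> frozenset:
        row = self.matrix.loc[colony]
        return frozenset(row.index[row == 1])

    def burdens(self) -> pd.Series:
        """Per-colony mutation counts (missing entries excluded)."""
        return (self.matrix == 1).sum(axis=1)


@dataclass
class ColonyClusters:
    """Clone assignment per colony from shared trunk mutations."""

    assignments: pd.Series           # colony -> clone label ("WT" for none)
    ambiguous: pd.Series             # colony -> bool (conflicting membership)
    trunks: dict                     # clone label -> frozenset of trunk variants


def cluster_colonies(matrix: BinaryMutationMatrix, min_shared: int = 1) -> ColonyClusters:
    """Group colonies into clones by shared trunk mutations.

    Colonies sharing at least ``min_shared`` variants are linked; connected
    components form clones and each clone's trunk is the intersection of
    its members' variant sets.  Colonies sharing nothing with anyone are
    labelled WT.  A component whose common trunk ends up smaller than
    ``min_shared`` is flagged ambiguous (conflicting membership), not an
    error.
    """
    if matrix.matrix.empty:
        raise InputError("empty mutation matrix")
    colonies = matrix.colonies
    carr_mask = matrix.matrix.to_numpy() == 1
    names = matrix.matrix.columns.to_numpy()
    shared_cols = carr_mask.sum(axis=0) >= 2
    sets = {c: frozenset(names[carr_mask[i] & shared_cols])
            for i, c in enumerate(colonies)}

    parent = {c: c for c in colonies}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, ci in enumerate(colonies):
        for cj in colonies[i + 1:]:
            if len(sets[ci] & sets[cj]) >= min_shared:
                parent[find(ci)] = find(cj)

    comps: dict[str, list] = {}
    for c in colonies:
        comps.setdefault(find(c), []).append(c)
    groups = [sorted(m) for m in comps.values() if not (len(m) == 1 and not sets[m[0]])]
    singles = [m[0] for m in comps.values() if len(m) == 1 and not sets[m[0]]]
    groups.sort(key=lambda g: (-len(g), g[0]))

    assign = pd.Series("WT", index=pd.Index(colonies, name="colony"), dtype=object)
    ambig = pd.Series(False, index=assign.index)
    trunks = {}
    for i, members in enumerate(groups, start=1):
        label = f"clone{i}"
        trunk = frozenset.intersection(*(sets[c] for c in members)) if members else frozenset()
        trunks[label] = trunk
        for c in members:
            assign[c] = label
            if len(trunk) < min_shared:
                ambig[c] = True
    for c in singles:
        assign[c] = "WT"
    return ColonyClusters(assignments=assign, ambiguous=ambig, trunks=trunks)


@dataclass
class CloneNode:
    """Tree node; ``mutations`` were acquired on the incoming branch."""

    name: str
    mutations: tuple = ()
    children: list = field(default_factory=list)
    parent: "CloneNode | None" = None

    @property
    def branch_length(self) -> int:
        return len(self.mutations)

    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "CloneNode") -> "CloneNode":
        child.parent = self
        self.children.append(child)
        return child


class CloneTree:
    """Rooted clone phylogeny with branch lengths in mutation counts."""

    def __init__(self, root: CloneNode):
        self.root = root

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self):
        return [n for n in self.iter_nodes() if n.is_leaf()]

    def find_branch(self, mutation: str) -> CloneNode:
        hits = [n for n in self.iter_nodes() if mutation in n.mutations]
        if not hits:
            raise CloneSpliceError(f"mutation {mutation!r} not present on any branch")
        if len(hits) > 1:
            raise CloneSpliceError(f"mutation {mutation!r} present on multiple branches")
        return hits[0]

    def mutations_above(self, node: CloneNode) -> int:
        """Total mutation count on branches strictly between root and node."""
        count, cur = 0, node.parent
        while cur is not None:
            count += cur.branch_length
            cur = cur.parent
        return count

    # Newick serialization: internal labels carry the branch mutation list
    # joined by '|'; leaves are colony names with zero-length branches.
    def to_newick(self) -> str:
        def render(node):
            label = "|".join(node.mutations) if node.mutations else node.name
            if node.is_leaf():
                return f"{label}:{node.branch_length}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){label}:{node.branch_length}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner}){self.root.name};"

    @classmethod
    def from_newick(cls, text: str) -> "CloneTree":
        text = text.strip()
        if not text.endswith(";"):
            raise InputError("Newick string must end with ';'")
        s, pos = text[:-1], 0

        def parse_label():
            nonlocal pos
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            return s[start:pos]

        def parse_node():
            nonlocal pos
            node = CloneNode("")
            if pos < len(s) and s[pos] == "(":
                pos += 1
                while True:
                    node.add(parse_node())
                    if pos < len(s) and s[pos] == ",":
                        pos += 1
                        continue
                    break
                if pos >= len(s) or s[pos] != ")":
                    raise InputError("unbalanced parentheses in Newick string")
                pos += 1
            label = parse_label()
            if pos < len(s) and s[pos] == ":":
                pos += 1
                parse_label()  # branch length is implied by the mutation count
            node.name = label
            if not node.is_leaf():
                node.mutations = tuple(label.split("|")) if label else ()
            return node

        root = parse_node()
        if pos != len(s):
            raise InputError(f"trailing characters in Newick string at position {pos}")
        root.mutations = ()
        root.name = root.name or "root"
        return cls(root)


def _variant_groups(matrix: BinaryMutationMatrix):
    """Merge variants with identical carrier sets; drop carrier-free ones."""
    carr_mask = matrix.matrix.to_numpy() == 1
    names = matrix.matrix.columns.to_numpy()
    colonies = matrix.matrix.index.to_numpy()
    by_rows: dict[tuple, list] = {}
    for j in range(carr_mask.shape[1]):
        rows = tuple(np.flatnonzero(carr_mask[:, j]))
        if rows:
            by_rows.setdefault(rows, []).append(names[j])
    groups = [(frozenset(colonies[list(rows)]), tuple(sorted(vs)))
              for rows, vs in by_rows.items()]
    groups.sort(key=lambda g: (-len(g[0]), g[1][0]))
    return groups


def check_three_gamete(matrix: BinaryMutationMatrix) -> None:
    """Raise :class:`IncompatibleMatrixError` on the first violating pair."""
    groups = _variant_groups(matrix)
    for i, (ca, va) in enumerate(groups):
        for cb, vb in groups[i + 1:]:
            inter = ca & cb
            if inter and not (ca <= cb or cb <= ca):
                raise IncompatibleMatrixError((va[0], vb[0]))


def build_clone_tree(matrix: BinaryMutationMatrix) -> CloneTree:
    """Perfect phylogeny by nested containment of variant carrier-sets.

    Variants with identical carrier sets merge onto one branch (ordered
    lexicographically); the parent of each branch is the smallest strictly
    containing carrier set.  Colonies attach as zero-length leaves under
    the deepest branch carrying them; colonies with no mutations hang off
    the root (WT).
    """
    if matrix.matrix.empty:
        raise InputError("empty mutation matrix")
    check_three_gamete(matrix)
    groups = _variant_groups(matrix)
    root = CloneNode("root")
    placed: list[tuple[frozenset, CloneNode]] = []
    for carr, variants in groups:
        parent_node, parent_size = root, None
        for pc, pn in placed:
            if carr <= pc and (parent_size is None or len(pc) < parent_size):
                parent_node, parent_size = pn, len(pc)
        node = parent_node.add(CloneNode(name="|".join(variants), mutations=variants))
        placed.append((carr, node))
    for colony in matrix.colonies:
        host, host_size = root, None
        for pc, pn in placed:
            if colony in pc and (host_size is None or len(pc) < host_size):
                host, host_size = pn, len(pc)
        host.add(CloneNode(name=str(colony)))
    return CloneTree(root)


@dataclass
class MutationRateEstimate:
    """Somatic mutation rate per year with an exact 95% profile CI."""

    rate_per_year: float
    ci_low: float
    ci_high: float
    n_colonies: int
    total_burden: int
    total_age_years: float
    confidence: float = 0.95


def _poisson_count_interval(count: int, confidence: float) -> tuple[float, float]:
    """Exact (Garwood) equal-tail interval for a Poisson mean given a count."""
    alpha = 1.0 - confidence
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2.0
    return float(lo), float(hi)


def estimate_mutation_rate(burdens, ages, confidence: float = 0.95) -> MutationRateEstimate:
    """Poisson regression through the origin of mutation burden on age.

    Under burden_i ~ Poisson(rate x age_i) the MLE is sum(burden)/sum(age)
    and the profile CI is the exact Poisson interval for the total count
    scaled by total age.  Stratify by clone by calling this per subgroup.
    """
    burdens = np.asarray(burdens, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if burdens.shape != ages.shape or burdens.ndim != 1 or len(burdens) == 0:
        raise InputError("burdens and ages must be equal-length non-empty vectors")
    if np.any(burdens < 0) or np.any(ages < 0):
        raise InputError("burdens and ages must be non-negative")
    total_age = float(ages.sum())
    if total_age <= 0:
        raise InputError("all ages are zero; rate is undefined")
    total = int(round(float(burdens.sum())))
    lo, hi = _poisson_count_interval(total, confidence)
    return MutationRateEstimate(
        rate_per_year=total / total_age,
        ci_low=lo / total_age,
        ci_high=hi / total_age,
        n_colonies=len(burdens),
        total_burden=total,
        total_age_years=total_age,
        confidence=confidence,
    )


@dataclass
class AgeInterval:
    """Estimated age window (years from birth) for a mutation's acquisition."""

    mutation_id: str
    lower_bound_years: float
    point_estimate_years: float
    upper_bound_years: float
    confidence: float = 0.95

    def __post_init__(self):
        if not (0 <= self.lower_bound_years <= self.point_estimate_years
                <= self.upper_bound_years):
            raise InputError("age interval bounds must satisfy 0 <= lower <= point <= upper")


def date_acquisition(
    tree: CloneTree,
    rate_per_year: float,
    driver: str,
    age_at_sampling: float,
    confidence: float = 0.95,
) -> AgeInterval:
    """Molecular-clock age interval for when a driver mutation was acquired.

    The driver's branch spans, in molecular time, the interval between the
    mutation count accumulated before the branch (m_before) and through its
    end (m_through).  Each endpoint carries exact Poisson count uncertainty:
    the 95% bounds are the Garwood interval limits of the two counts,
    divided by the clock rate, with the upper bound clamped to the donor's
    age at sampling.
    """
    if rate_per_year <= 0:
        raise InputError("clock rate must be positive")
    branch = tree.find_branch(driver)
    m_before = tree.mutations_above(branch)
    m_through = m_before + branch.branch_length
    lo_count, _ = _poisson_count_interval(m_before, confidence)
    _, hi_count = _poisson_count_interval(m_through, confidence)
    lower = lo_count / rate_per_year
    upper = min(hi_count / rate_per_year, float(age_at_sampling))
    point = (m_before + m_through) / (2.0 * rate_per_year)
    point = min(max(point, lower), upper)
    return AgeInterval(
        mutation_id=driver,
        lower_bound_years=lower,
        point_estimate_years=point,
        upper_bound_years=upper,
        confidence=confidence,
    )
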