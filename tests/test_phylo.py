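"""Perfect-phylogeny reconstruction against an exhaustive containment
oracle, clone clustering recovery, clock-rate estimation and dating."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonesplice.errors import CloneSpliceError, IncompatibleMatrixError, InputError
from clonesplice.phylo import (
    BinaryMutationMatrix,
    CloneNode,
    CloneTree,
    build_clone_tree,
    cluster_colonies,
    date_acquisition,
    estimate_mutation_rate,
)
from clonesplice.synth import SimulationConfig, simulate_colonies


def matrix_from_dict(d):
    """d: colony -> list of variants. Values become a 0/1 DataFrame."""
    variants = sorted({v for vs in d.values() for v in vs})
    mat = pd.DataFrame(0, index=pd.Index(sorted(d), name="colony"), columns=variants)
    for c, vs in d.items():
        for v in vs:
            mat.loc[c, v] = 1
    return BinaryMutationMatrix(matrix=mat)


# -- clustering -------------------------------------------------------------

def test_two_disjoint_trunks_form_two_clones():
    m = matrix_from_dict({
        "c1": ["d1", "t1"], "c2": ["d1", "t1"],
        "c3": ["d2", "t2"], "c4": ["d2", "t2"],
        "c5": [],
    })
    res = cluster_colonies(m)
    assert res.assignments["c1"] == res.assignments["c2"]
    assert res.assignments["c3"] == res.assignments["c4"]
    assert res.assignments["c1"] != res.assignments["c3"]
    assert res.assignments["c5"] == "WT"
    assert not res.ambiguous.any()


def test_cluster_recovers_simulated_truth_exactly():
    cfg = SimulationConfig(seed=31, colonies_per_compartment=40,
                           mutation_rate_per_year=18.0, donor_ages=(66.0,))
    _, matrix, truth = simulate_colonies(cfg)
    res = cluster_colonies(matrix)
    truth_lab = pd.Series(truth.colony_clones)
    correct = 0
    for label in res.assignments.unique():
        members = res.assignments[res.assignments == label].index
        want = "WT" if label == "WT" else truth_lab[members].mode()[0]
        correct += int((truth_lab[members] == want).sum())
    assert correct / len(truth_lab) >= 0.99


def test_cluster_degrades_gracefully_with_genotype_error():
    cfg = SimulationConfig(seed=31, colonies_per_compartment=40,
                           mutation_rate_per_year=18.0, donor_ages=(66.0,),
                           genotype_error_rate=0.01)
    _, matrix, truth = simulate_colonies(cfg)
    res = cluster_colonies(matrix, min_shared=2)
    truth_lab = pd.Series(truth.colony_clones)
    correct = 0
    for label in res.assignments.unique():
        members = res.assignments[res.assignments == label].index
        want = "WT" if label == "WT" else truth_lab[members].mode()[0]
        correct += int((truth_lab[members] == want).sum())
    assert correct / len(truth_lab) >= 0.8


# -- tree construction ------------------------------------------------------

def test_nested_carrier_sets_build_a_chain():
    m = matrix_from_dict({
        "c1": ["A"], "c2": ["A", "B"], "c3": ["A", "B", "C"],
    })
    tree = build_clone_tree(m)
    node = tree.root
    chain = []
    while node.children:
        internal = [c for c in node.children if not c.is_leaf()]
        chain.append(tuple(node.mutations))
        assert len(internal) <= 1
        if not internal:
            break
        node = internal[0]
    labels = [tuple(n.mutations) for n in _internal_nodes(tree)]
    assert (("A",) in labels) and (("B",) in labels) and (("C",) in labels)
    # A's node must be an ancestor of B's, B's of C's
    a = tree.find_branch("A")
    b = tree.find_branch("B")
    c = tree.find_branch("C")
    assert b.parent is a and c.parent is b


def _internal_nodes(tree):
    return [n for n in tree.iter_nodes() if n.mutations]


def test_forbidden_gamete_pattern_raises():
    m = matrix_from_dict({"c1": ["A"], "c2": ["B"], "c3": ["A", "B"]})
    with pytest.raises(IncompatibleMatrixError) as exc:
        build_clone_tree(m)
    assert set(exc.value.pair) == {"A", "B"}


def _random_matrix(rng, compatible):
    n_var = int(rng.integers(1, 7))
    n_col = int(rng.integers(1, 9))
    variants = [f"v{i}" for i in range(n_var)]
    colonies = [f"c{i}" for i in range(n_col)]
    if compatible:
        # sample variants along a random tree, colonies at random nodes
        parent = {}
        for i, v in enumerate(variants):
            choices = [None] + variants[:i]
            parent[v] = choices[int(rng.integers(0, len(choices)))]
        def path(v):
            out = []
            while v is not None:
                out.append(v)
                v = parent[v]
            return out
        mat = pd.DataFrame(0, index=colonies, columns=variants)
        for c in colonies:
            attach = [None] + variants
            node = attach[int(rng.integers(0, len(attach)))]
            if node is not None:
                mat.loc[c, path(node)] = 1
    else:
        mat = pd.DataFrame(rng.integers(0, 2, size=(n_col, n_var)),
                           index=colonies, columns=variants)
    mat.index.name = "colony"
    return BinaryMutationMatrix(matrix=mat)


def _oracle_violation(mat):
    """Brute-force three-gamete check over all variant pairs."""
    arr = mat.matrix.to_numpy()
    n = arr.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[:, i], arr[:, j]
            if (((a == 1) & (b == 0)).any() and ((a == 0) & (b == 1)).any()
                    and ((a == 1) & (b == 1)).any()):
                return True
    return False


def _oracle_parents(mat):
    """Containment poset over merged carrier sets: the unique perfect
    phylogeny's parent map, computed independently of the tree builder."""
    carriers = {}
    for v in mat.variants:
        carr = frozenset(c for c in mat.colonies if mat.matrix.at[c, v] == 1)
        if carr:
            carriers.setdefault(carr, []).append(v)
    groups = {carr: tuple(sorted(vs)) for carr, vs in carriers.items()}
    parents = {}
    for carr, vs in groups.items():
        supersets = [c2 for c2 in groups if carr < c2]
        best = None
        for c2 in supersets:
            if best is None or len(c2) < len(best):
                best = c2
        parents[vs] = groups[best] if best is not None else "root"
    return parents


def test_tree_matches_exhaustive_containment_oracle():
    """For hundreds of random matrices with <=6 variants and <=8 colonies,
    the built tree reproduces the containment-poset oracle exactly, and
    every three-gamete violation raises the incompatibility error."""
    rng = np.random.default_rng(99)
    n_compat = n_violate = 0
    for trial in range(300):
        mat = _random_matrix(rng, compatible=bool(rng.integers(0, 2)))
        if _oracle_violation(mat):
            n_violate += 1
            with pytest.raises(IncompatibleMatrixError):
                build_clone_tree(mat)
            continue
        n_compat += 1
        tree = build_clone_tree(mat)
        got = {}
        for node in tree.iter_nodes():
            if not node.mutations:
                continue
            parent = node.parent
            while parent is not None and not parent.mutations and parent.parent is not None:
                parent = parent.parent
            got[tuple(node.mutations)] = (
                tuple(parent.mutations) if parent is not None and parent.mutations
                else "root"
            )
        assert got == _oracle_parents(mat)
        # path-union invariant: mutations along each colony's path equal its set
        for leaf in tree.leaves():
            path_muts = set()
            node = leaf
            while node is not None:
                path_muts.update(node.mutations)
                node = node.parent
            assert path_muts == set(mat.variant_set(leaf.name))
    assert n_compat > 50 and n_violate > 50


def test_newick_round_trip_preserves_topology_and_counts():
    m = matrix_from_dict({
        "c1": ["d1", "t1", "p1"], "c2": ["d1", "t1"],
        "c3": ["d2"], "c4": [],
    })
    tree = build_clone_tree(m)
    text = tree.to_newick()
    back = CloneTree.from_newick(text)
    assert back.to_newick() == text
    orig = sorted((tuple(n.mutations), n.branch_length) for n in tree.iter_nodes())
    rt = sorted((tuple(n.mutations), n.branch_length) for n in back.iter_nodes())
    assert orig == rt


def test_newick_is_parseable_by_dendropy():
    dendropy = pytest.importorskip("dendropy")
    m = matrix_from_dict({"c1": ["d1", "t1"], "c2": ["d1"], "c3": []})
    tree = build_clone_tree(m)
    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert {leaf.taxon.label for leaf in dt.leaf_node_iter()} == {"c1", "c2", "c3"}
    total = sum(e.length or 0 for e in dt.edges())
    assert total == sum(n.branch_length for n in tree.iter_nodes())


# -- mutation rate ----------------------------------------------------------

def test_exact_burdens_recover_rate():
    ages = np.array([10.0, 20.0, 30.0])
    est = estimate_mutation_rate(2.0 * ages, ages)
    assert est.rate_per_year == pytest.approx(2.0)
    assert est.ci_low < 2.0 < est.ci_high


def test_single_colony_ratio():
    est = estimate_mutation_rate([60], [30.0])
    assert est.rate_per_year == pytest.approx(2.0)


def test_zero_ages_rejected():
    with pytest.raises(InputError):
        estimate_mutation_rate([5, 3], [0.0, 0.0])


def test_rate_ci_coverage_in_simulation():
    """Simulated Poisson burdens at 18/yr, 20 colonies: the true rate falls
    inside the 95% CI in >=90% of 100 reps."""
    rng = np.random.default_rng(17)
    hits = 0
    for _ in range(100):
        ages = rng.uniform(40, 80, 20)
        burdens = rng.poisson(18.0 * ages)
        est = estimate_mutation_rate(burdens, ages)
        hits += int(est.ci_low <= 18.0 <= est.ci_high)
    assert hits >= 90


# -- dating -----------------------------------------------------------------

def _chain_tree(n_before, n_branch, driver="DRV"):
    root = CloneNode("root")
    node = root
    if n_before:
        node = node.add(CloneNode("pre", tuple(f"m{i}" for i in range(n_before))))
    branch_muts = (driver,) + tuple(f"b{i}" for i in range(n_branch - 1))
    node = node.add(CloneNode("drv", branch_muts))
    node.add(CloneNode("leaf"))
    return CloneTree(root)


def test_driver_on_first_branch_has_lower_bound_zero():
    iv = date_acquisition(_chain_tree(0, 5), rate_per_year=2.0,
                          driver="DRV", age_at_sampling=60.0)
    assert iv.lower_bound_years == 0.0
    assert iv.upper_bound_years <= 60.0


def test_upper_bound_clamped_to_age():
    iv = date_acquisition(_chain_tree(0, 500), rate_per_year=1.0,
                          driver="DRV", age_at_sampling=60.0)
    assert iv.upper_bound_years == 60.0


def test_dating_is_monotone_in_prior_mutations():
    a = date_acquisition(_chain_tree(5, 5), 2.0, "DRV", 80.0)
    b = date_acquisition(_chain_tree(20, 5), 2.0, "DRV", 80.0)
    assert b.lower_bound_years > a.lower_bound_years
    assert b.upper_bound_years > a.upper_bound_years


def test_missing_or_duplicated_driver_rejected():
    tree = _chain_tree(2, 3)
    with pytest.raises(CloneSpliceError):
        date_acquisition(tree, 2.0, "nope", 60.0)
    root = CloneNode("root")
    root.add(CloneNode("x", ("DRV",)))
    root.add(CloneNode("y", ("DRV",)))
    with pytest.raises(CloneSpliceError):
        date_acquisition(CloneTree(root), 2.0, "DRV", 60.0)


def test_dating_on_simulated_colonies_brackets_truth():
    cfg = SimulationConfig(seed=23, colonies_per_compartment=40,
                           acquisition_times={"SF3B1-N626D": 20.0, "SF3B1-K666N": 30.0})
    _, matrix, truth = simulate_colonies(cfg)
    tree = build_clone_tree(matrix)
    rate = estimate_mutation_rate(matrix.burdens().to_numpy(),
                                  matrix.age_years.to_numpy()).rate_per_year
    for driver, t_true in truth.acquisition_times.items():
        iv = date_acquisition(tree, rate, driver, 66.0)
        assert iv.lower_bound_years <= t_true <= iv.upper_bound_years


def test_missing_entries_excluded_from_carrier_sets():
    mat = pd.DataFrame(
        [[1.0, np.nan], [1.0, 1.0], [0.0, 0.0]],
        index=pd.Index(["c1", "c2", "c3"], name="colony"), columns=["A", "B"],
    )
    m = BinaryMutationMatrix(matrix=mat)
    assert m.carriers("B") == frozenset({"c2"})
    tree = build_clone_tree(m)  # B nested under A: no violation
    assert tree.find_branch("B").parent is tree.find_branch("A")
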