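"""PSI/dPSI arithmetic, event-geometry classification, the common and
mutation-biased filters, and coding-consequence annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonesplice.errors import InputError
from clonesplice.splice import (
    GenomeAnnotation,
    Junction,
    JunctionCountTable,
    SpliceEvent,
    Transcript,
    annotate_consequence,
    classify_event,
    compute_dpsi,
    compute_psi,
    dpsi_table,
    events_from_junctions,
    filter_events,
    pseudobulk_by_genotype,
    psi_table,
)
from clonesplice.synth import simulate_junction_counts


@pytest.fixture(scope="module")
def toy_annotation():
    """One plus-strand gene: exons 0-100, 200-300, 400-500, fully coding
    except the last 40 nt (3' UTR)."""
    t = Transcript(
        "tx1", "g1", "chr1", "+",
        exons=((0, 100), (200, 300), (400, 500)),
        cds=((0, 100), (200, 300), (400, 460)),
    )
    return GenomeAnnotation([t])


# -- PSI --------------------------------------------------------------------

def _event(inc, exc, etype="A3SS", **kw):
    return SpliceEvent("e1", "g1", etype, tuple(inc), tuple(exc), chrom="chr1", **kw)


def test_psi_arithmetic():
    ev = _event(["j1"], ["j2"])
    assert compute_psi(ev, {"j1": 9, "j2": 1}, min_coverage=1) == pytest.approx(90.0)


def test_psi_missing_below_coverage():
    ev = _event(["j1"], ["j2"])
    assert np.isnan(compute_psi(ev, {"j1": 0, "j2": 0}, min_coverage=1))
    assert np.isnan(compute_psi(ev, {"j1": 5, "j2": 4}, min_coverage=10))
    assert compute_psi(ev, {"j1": 5, "j2": 5}, min_coverage=10) == pytest.approx(50.0)


def test_absent_junction_counts_as_zero():
    ev = _event(["j1"], ["jX"])
    assert compute_psi(ev, {"j1": 12}, min_coverage=10) == pytest.approx(100.0)


# -- pseudobulk -------------------------------------------------------------

def _tiny_table():
    counts = pd.DataFrame(
        [[5, 1], [3, 2], [0, 7]],
        index=pd.Index(["cell1", "cell2", "cell3"], name="cell"),
        columns=["chr1:100-200:+", "chr1:100-215:+"],
    )
    junctions = pd.DataFrame(
        {"chrom": "chr1", "start": [100, 100], "end": [200, 215],
         "strand": "+", "kind": "junction"},
        index=pd.Index(counts.columns, name="junction_id"),
    )
    genotypes = pd.Series(["cloneA", "cloneA", "cloneB"], index=counts.index)
    return JunctionCountTable(counts, junctions, genotypes)


def test_pseudobulk_sums_and_preserves_totals():
    table = _tiny_table()
    grouped = pseudobulk_by_genotype(table)
    assert list(grouped.counts.index) == ["cloneA", "cloneB"]
    assert grouped.counts.loc["cloneA"].tolist() == [8, 3]
    np.testing.assert_array_equal(grouped.counts.sum(axis=0).to_numpy(),
                                  table.counts.sum(axis=0).to_numpy())


def test_pseudobulk_identity_when_one_cell_per_group():
    table = _tiny_table()
    table.genotypes[:] = ["g1", "g2", "g3"]
    grouped = pseudobulk_by_genotype(table)
    np.testing.assert_array_equal(
        np.sort(grouped.counts.to_numpy(), axis=0),
        np.sort(table.counts.to_numpy(), axis=0),
    )


def test_pseudobulk_rejects_unlabelled_cells():
    table = _tiny_table()
    table.genotypes["cell2"] = np.nan
    with pytest.raises(InputError):
        pseudobulk_by_genotype(table)


def test_pseudobulk_matches_generator_totals(default_junction_run):
    _, table, _, truth = default_junction_run
    grouped = pseudobulk_by_genotype(table)
    jid = truth.event_defs["ev0000"]["inclusion"][0]
    manual = table.counts.loc[table.genotypes == "cloneA", jid].sum()
    assert grouped.counts.at["cloneA", jid] == manual


# -- classification ---------------------------------------------------------

def test_alt_3ss_geometry_and_offset(toy_annotation):
    inc = [Junction("chr1", 100, 215, "+")]
    exc = [Junction("chr1", 100, 200, "+")]
    assert classify_event(inc, exc, toy_annotation) == ("A3SS", 15)


def test_strand_flip_swaps_alt_site_labels(toy_annotation):
    inc = [Junction("chr1", 100, 215, "-")]
    exc = [Junction("chr1", 100, 200, "-")]
    assert classify_event(inc, exc, toy_annotation) == ("A5SS", 15)


def test_strand_antisymmetry_property(toy_annotation):
    """Flipping strand swaps A3SS and A5SS, changing nothing else."""
    rng = np.random.default_rng(5)
    swap = {"A3SS": "A5SS", "A5SS": "A3SS"}
    for _ in range(50):
        start = int(rng.integers(0, 1000))
        end = start + int(rng.integers(10, 500))
        if rng.random() < 0.5:
            other = Junction("chr1", start, end + int(rng.integers(1, 50)), "+")
        else:
            other = Junction("chr1", start + int(rng.integers(1, min(50, end - start))), end, "+")
        base = Junction("chr1", start, end, "+")
        t_plus, off_plus = classify_event([base], [other], toy_annotation)
        t_minus, off_minus = classify_event(
            [base._replace(strand="-")], [other._replace(strand="-")], toy_annotation)
        assert t_minus == swap[t_plus] and off_minus == off_plus


def test_exon_skip_geometry(toy_annotation):
    inc = [Junction("chr1", 100, 200, "+"), Junction("chr1", 300, 400, "+")]
    exc = [Junction("chr1", 100, 400, "+")]
    etype, off = classify_event(inc, exc, toy_annotation)
    assert etype == "SE" and off == 100  # skipped exon 200-300


def test_retained_intron_uses_proxy(toy_annotation):
    inc = [Junction("chr1", 100, 200, "+", kind="intron_proxy")]
    exc = [Junction("chr1", 100, 200, "+")]
    assert classify_event(inc, exc, toy_annotation) == ("RI", 100)


def test_mutually_exclusive_exons():
    tx_a = Transcript("ta", "g1", "chr1", "+", ((0, 100), (200, 300), (600, 700)))
    tx_b = Transcript("tb", "g1", "chr1", "+", ((0, 100), (400, 500), (600, 700)))
    ann = GenomeAnnotation([tx_a, tx_b])
    inc = [Junction("chr1", 100, 200, "+"), Junction("chr1", 300, 600, "+")]
    exc = [Junction("chr1", 100, 400, "+"), Junction("chr1", 500, 600, "+")]
    etype, _ = classify_event(inc, exc, ann)
    assert etype == "MXE"


def test_unmatched_geometry_is_unclassified(toy_annotation):
    inc = [Junction("chr1", 100, 200, "+")]
    exc = [Junction("chr2", 100, 215, "+")]
    assert classify_event(inc, exc, toy_annotation)[0] == "unclassified"


# -- dPSI and filters -------------------------------------------------------

def test_dpsi_against_control_mean():
    assert compute_dpsi(50.0, [50.0, 50.0, 50.0]) == pytest.approx(0.0)
    assert compute_dpsi(80.0, [60.0, 62.0, 58.0]) == pytest.approx(20.0)
    assert np.isnan(compute_dpsi(80.0, [np.nan, np.nan]))
    assert np.isnan(compute_dpsi(np.nan, [60.0]))
    assert compute_dpsi(80.0, [np.nan, 70.0]) == pytest.approx(10.0)


@pytest.mark.parametrize("da,db,expected", [
    (15.0, 12.0, "common"),
    (-15.0, -12.0, "common"),
    (15.0, 1.0, "A-biased"),
    (1.0, 15.0, "B-biased"),
    (-15.0, 1.0, "A-biased"),
    (1.5, 1.0, "null"),
    (2.0, 5.0, "indeterminate"),
    (5.0, 2.0, "indeterminate"),
    (15.0, -12.0, "indeterminate"),   # discordant signs under the default rule
    (np.nan, 5.0, "indeterminate"),
])
def test_filter_classification_boundaries(da, db, expected):
    rec = pd.DataFrame({"dpsi_cloneA": [da], "dpsi_cloneB": [db]}, index=["e"])
    out = filter_events(rec)
    assert out.loc["e", "classification"] == expected


def test_sign_concordance_flag():
    rec = pd.DataFrame({"dpsi_cloneA": [15.0], "dpsi_cloneB": [-12.0]}, index=["e"])
    out = filter_events(rec, require_sign_concordance=False)
    assert out.loc["e", "classification"] == "common"


def test_clone_clone_dpsi_and_diagonal_band():
    rec = pd.DataFrame({"dpsi_cloneA": [15.0, 30.0], "dpsi_cloneB": [12.0, 5.0]},
                       index=["e1", "e2"])
    out = filter_events(rec)
    assert out.loc["e1", "clone_clone_dpsi"] == pytest.approx(3.0)
    assert bool(out.loc["e1", "within_diagonal_band"]) is True
    assert bool(out.loc["e2", "within_diagonal_band"]) is False


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    da=st.floats(min_value=-100, max_value=100, allow_nan=False),
    db=st.floats(min_value=-100, max_value=100, allow_nan=False),
    bias=st.floats(min_value=0.5, max_value=10),
)
def test_classification_is_a_partition_and_threshold_monotone(da, db, bias):
    rec = pd.DataFrame({"dpsi_cloneA": [da], "dpsi_cloneB": [db]}, index=["e"])
    base = filter_events(rec)["classification"].iloc[0]
    assert base in {"common", "A-biased", "B-biased", "indeterminate", "null"}
    raised = filter_events(rec, bias_threshold=2.0 + bias)["classification"].iloc[0]
    # raising the bias threshold can never turn a biased event into common
    if base in ("A-biased", "B-biased"):
        assert raised != "common"


# -- consequence annotation -------------------------------------------------

def _a3ss_event(offset, lo, hi):
    return SpliceEvent("e1", "g1", "A3SS",
                       (f"chr1:{100}-{hi}:+",), (f"chr1:{100}-{lo}:+",),
                       chrom="chr1", strand="+", cryptic_offset_nt=offset,
                       region=(lo, hi))


def test_in_frame_and_frameshift(toy_annotation):
    assert annotate_consequence(_a3ss_event(15, 185, 200), toy_annotation) == "in-frame"
    assert annotate_consequence(_a3ss_event(14, 186, 200), toy_annotation) == "frameshift"


def test_utr_event_is_noncoding(toy_annotation):
    ev = SpliceEvent("e1", "g1", "A3SS", ("i",), ("x",), chrom="chr1", strand="+",
                     cryptic_offset_nt=15, region=(470, 490))  # in the 3' UTR
    assert annotate_consequence(ev, toy_annotation) == "noncoding"


def test_intergenic_event_is_unannotated(toy_annotation):
    ev = SpliceEvent("e1", "gX", "A3SS", ("i",), ("x",), chrom="chr9", strand="+",
                     cryptic_offset_nt=15, region=(100, 115))
    assert annotate_consequence(ev, toy_annotation) == "unannotated"


# -- end to end on generator output -----------------------------------------

def test_event_reconstruction_matches_generator(default_junction_run):
    _, table, annotation, truth = default_junction_run
    grouped = pseudobulk_by_genotype(table)
    events = events_from_junctions(grouped, annotation)
    got = {tuple(sorted(e.inclusion)): e.event_type for e in events}
    assert len(events) == len(truth.event_defs)
    for d in truth.event_defs.values():
        key = tuple(sorted(d["inclusion"]))
        assert got[key] == d["event_type"]


def test_end_to_end_classification_and_invariants(default_junction_run):
    _, table, annotation, truth = default_junction_run
    grouped = pseudobulk_by_genotype(table)
    events = events_from_junctions(grouped, annotation)
    psis = psi_table(events, grouped)
    vals = psis.psi.to_numpy()
    assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 100.0
    records = filter_events(dpsi_table(psis))
    d = records[["dpsi_cloneA", "dpsi_cloneB"]].to_numpy()
    assert np.nanmin(d) >= -100.0 and np.nanmax(d) <= 100.0
    truth_by_key = {tuple(sorted(v["inclusion"])): v["truth_label"]
                    for v in truth.event_defs.values()}
    null_dpsis = []
    for e in events:
        label = truth_by_key[tuple(sorted(e.inclusion))]
        call = records.at[e.event_id, "classification"]
        if label == "null":
            null_dpsis.append(records.at[e.event_id, "dpsi_cloneA"])
        if label in ("A-biased", "B-biased", "common"):
            assert call == label
    assert abs(np.nanmean(null_dpsis)) < 2.0


def test_generated_tables_have_consistent_genotypes(default_junction_run):
    cfg, table, _, _ = default_junction_run
    labels = set(table.genotypes)
    assert labels == {"cloneA", "cloneB"} | {f"NBM{i+1}" for i in range(cfg.n_control_donors)}
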