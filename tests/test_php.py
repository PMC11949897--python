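"""Identity screen, correlation screen and the dual-evidence merge."""

import numpy as np
import pandas as pd
import pytest

from mycohub.io import (
    AsvCountTable,
    MetaboliteTable,
    ReferenceStrainSet,
    SampleMetadata,
    SequenceSet,
)
from mycohub.php import (
    kendall_tau_b,
    merge_php_calls,
    pairwise_identity,
    php_tissue_summary,
    screen_by_correlation,
    screen_by_identity,
    tissue_mean_abundance,
)


def test_identity_identical_sequences():
    seq = "ACGTACGTAC" * 10
    ident, cols = pairwise_identity(seq, seq)
    assert ident == pytest.approx(100.0)
    assert cols == len(seq)


def test_identity_single_mismatch():
    seq = "A" * 50 + "C" + "A" * 49
    other = "A" * 100
    ident, cols = pairwise_identity(seq, other)
    assert cols == 100
    assert ident == pytest.approx(99.0)


def test_identity_overhang_excluded():
    # query is an internal substring: terminal gaps are free and excluded
    ref = "GGGG" + "ACGTACGTACGTACGTACGT" + "CCCC"
    query = "ACGTACGTACGTACGTACGT"
    ident, cols = pairwise_identity(query, ref)
    assert ident == pytest.approx(100.0)
    assert cols == len(query)


def test_identity_internal_gap_counts_in_denominator():
    ref = "ACGTACGTACGTACGTACGT"
    query = ref[:10] + ref[12:]  # 2-base internal deletion
    ident, cols = pairwise_identity(query, ref)
    assert cols == len(ref)
    assert ident == pytest.approx(100.0 * 18 / 20)


def test_identity_iupac_ambiguity_matches():
    ident, _ = pairwise_identity("ACGTN", "ACGTA")
    assert ident == pytest.approx(100.0)
    ident, _ = pairwise_identity("ACGTR", "ACGTC")  # R = A/G, no intersection
    assert ident == pytest.approx(80.0)


def test_identity_rejects_empty():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


def _refs(seqs: dict[str, str]) -> ReferenceStrainSet:
    info = pd.DataFrame(
        {"genus": ["Penicillium"] * len(seqs), "source_tag": ["t"] * len(seqs)},
        index=pd.Index(list(seqs), name="strain_id"),
    )
    return ReferenceStrainSet(SequenceSet(dict(seqs)), info)


def test_screen_by_identity_threshold_inclusive():
    base = "ACGT" * 50  # 200 bp
    hit99 = base[:100] + "T" + base[101:]  # 1 mismatch -> 99.5%
    nohit = "".join("T" if c == "A" else c for c in base)  # far below
    at_97 = list(base)
    for pos in (10, 30, 50, 70, 90, 110):  # 6 mismatches -> exactly 97.0
        at_97[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[at_97[pos]]
    at_97 = "".join(at_97)
    asvs = SequenceSet({"h": hit99, "n": nohit, "b": at_97})
    hits = screen_by_identity(asvs, _refs({"r1": base}), identity_min=97.0)
    by_id = {h.asv_id: h for h in hits}
    assert set(by_id) == {"h", "b"}
    assert by_id["h"].identity == pytest.approx(99.5)
    assert by_id["b"].identity == pytest.approx(97.0)  # >= is inclusive
    assert by_id["h"].strain_id == "r1"


def test_screen_by_identity_prefilter_consistent():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    refs = {f"r{i}": "".join(rng.choice(bases, 120)) for i in range(3)}
    asvs = {f"a{i}": "".join(rng.choice(bases, 120)) for i in range(4)}
    # add one true near-copy
    asvs["close"] = refs["r1"][:60] + "A" + refs["r1"][61:]
    with_filter = screen_by_identity(SequenceSet(asvs), _refs(refs))
    without = screen_by_identity(SequenceSet(asvs), _refs(refs),
                                 prefilter_margin=None)
    assert [(h.asv_id, h.strain_id) for h in with_filter] == \
        [(h.asv_id, h.strain_id) for h in without]


def test_kendall_tau_b_hand_value():
    # pairs: (1,1)-(2,2) C, (1,1)-(2,3) C, (1,1)-(3,3) C, (2,2)-(2,3) tie-x,
    # (2,2)-(3,3) C, (2,3)-(3,3) tie-y -> tau-b = 4/sqrt(5*5) = 0.8
    assert kendall_tau_b([1, 2, 2, 3], [1, 2, 3, 3]) == pytest.approx(0.8)


def test_kendall_tau_b_constant_is_none():
    assert kendall_tau_b([1, 1, 1], [1, 2, 3]) is None
    with pytest.raises(ValueError):
        kendall_tau_b([1], [1])


def _screen_setup(taus_abund):
    tissues = ["t1", "t2", "t3", "t4"]
    means = pd.DataFrame(taus_abund, index=tissues)
    metab = MetaboliteTable(pd.DataFrame({
        "tissue": tissues, "compound": ["HupA"] * 4,
        "mean_concentration": [400.0, 300.0, 200.0, 100.0],
    }))
    return means, metab


def test_screen_by_correlation_strict_threshold():
    means, metab = _screen_setup({
        "mono": [4.0, 3.0, 2.0, 1.0],       # tau = 1 -> kept
        "anti": [1.0, 2.0, 3.0, 4.0],       # tau = -1 -> dropped
        "flat": [1.0, 1.0, 1.0, 1.0],       # undefined -> dropped
        "mid": [4.0, 3.0, 1.0, 2.0],        # tau = 2/3 -> kept at 0.4
    })
    out = screen_by_correlation(means, metab, "HupA", tau_min=0.4)
    assert set(out) == {"mono", "mid"}
    assert out["mono"] == pytest.approx(1.0)
    # strictly-above rule: raising the threshold just past tau excludes it
    out2 = screen_by_correlation(means, metab, "HupA", tau_min=0.67)
    assert set(out2) == {"mono"}
    # and tau exactly at the threshold never passes (strict >)
    out3 = screen_by_correlation(means, metab, "HupA", tau_min=1.0)
    assert out3 == {}


def test_screen_by_correlation_tissue_mismatch():
    means, metab = _screen_setup({"x": [1.0, 2.0, 3.0, 4.0]})
    bad = means.rename(index={"t4": "elsewhere"})
    with pytest.raises(ValueError, match="tissue sets differ"):
        screen_by_correlation(bad, metab, "HupA")


def test_tissue_mean_abundance(tiny_table, tiny_meta):
    means = tissue_mean_abundance(tiny_table, tiny_meta)
    # leaf = mean of s1 (66.67, 0, 33.33) and s2 (0, 80, 20)
    assert means.loc["leaf", "A1"] == pytest.approx((1000 / 15 + 0) / 2)
    assert means.loc["leaf", "A3"] == pytest.approx((500 / 15 + 20) / 2)


def test_merge_php_calls_union_arithmetic():
    from mycohub.php import IdentityHit

    hits = [IdentityHit("a", "r", 99.0, 100), IdentityHit("b", "r", 98.0, 100)]
    corr = {"b": 0.9, "c": 0.5}
    calls = merge_php_calls(hits, corr)
    counts = calls.counts()
    assert counts == {"n_clustering": 2, "n_correlation": 2, "n_both": 1,
                      "n_union": 3}
    frame = calls.to_frame()
    row_b = frame[frame["asv_id"] == "b"].iloc[0]
    assert row_b["evidence_clustering"] and row_b["evidence_correlation"]
    assert row_b["best_identity"] == pytest.approx(98.0)
    assert row_b["tau"] == pytest.approx(0.9)


def test_php_tissue_summary_rounding(tiny_table, tiny_meta):
    from mycohub.php import IdentityHit

    calls = merge_php_calls([IdentityHit("A1", "r", 99.0, 100)], {})
    summary = php_tissue_summary(calls, tiny_table, tiny_meta)
    # leaf detects A1, A2, A3 -> 1/3 rounds half-up to 33.33
    assert summary.loc["leaf", "n_asvs_detected"] == 3
    assert summary.loc["leaf", "percent_php"] == pytest.approx(33.33)


def test_php_recovery_on_synthetic(small_ds):
    hits = screen_by_identity(small_ds.sequences, small_ds.references,
                              identity_min=97.0)
    means = tissue_mean_abundance(small_ds.counts, small_ds.metadata)
    corr = screen_by_correlation(means, small_ds.metabolites, "HupA",
                                 tau_min=0.4)
    calls = merge_php_calls(hits, corr)
    truth = small_ds.truth.producer_asv_ids
    found = calls.asv_ids
    sensitivity = len(found & truth) / len(truth)
    assert sensitivity >= 0.8
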