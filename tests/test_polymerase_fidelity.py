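import numpy as np
import pytest

from imsatkit.polymerase_fidelity import (
    ColonyCounts,
    KIND_CODING,
    KIND_INT_DEL,
    KIND_INT_SUB,
    KIND_UNIT_INDEL,
    MutantRecord,
    MutationalEvent,
    apply_events,
    classify_events,
    correct_multiple_events,
    event_class_ef,
    mutant_frequency,
    pol_ef,
    spectrum_report,
    summarize,
)
from imsatkit.synthetic_data import (
    default_reporter_template,
    gen_mutant_collection,
)


# -- frequencies ----------------------------------------------------------------


@pytest.mark.parametrize(
    "fudr, cm, mf",
    [(0, 10_000, 0.0), (25, 50_000, 5e-4), (50_000, 50_000, 1.0)],
)
def test_mutant_frequency(fudr, cm, mf):
    assert mutant_frequency(ColonyCounts(fudr, cm)) == pytest.approx(mf)


def test_colony_counts_validation():
    with pytest.raises(ValueError):
        ColonyCounts(5, 0)
    with pytest.raises(ValueError):
        ColonyCounts(10, 5)


def test_pol_ef_subtraction_and_floor():
    assert pol_ef(5e-4, 1e-4, 1e-4) == pytest.approx(3e-4)
    assert pol_ef(1e-4, 1e-4, 0.0) == 0.0
    with pytest.warns(UserWarning):
        assert pol_ef(1e-5, 2e-5, 0.0) == 0.0


# -- event classification ---------------------------------------------------------


def test_unit_deletion_gt10_to_gt9(gt10_template):
    """[GT]_10 -> [GT]_9: one unit-based indel, detectable frameshift."""
    seq = gt10_template.sequence
    r0, r1 = gt10_template.repeat_span
    mutant = seq[: r1 - 2] + seq[r1:]
    events = classify_events(MutantRecord("t", mutant), gt10_template)
    assert len(events) == 1
    ev = events[0]
    assert ev.kind == KIND_UNIT_INDEL
    assert ev.ref == "GT" and ev.alt == ""
    assert ev.detectable  # net -2 is a frameshift
    assert apply_events(seq, events) == mutant


def test_interruption_removal_a3ta4_to_a7(apc_ims_template):
    """[A]_3 T [A]_4 -> [A]_7: deleting the interrupting T is an
    interruption-deletion, not a unit-based indel."""
    seq = apc_ims_template.sequence
    r0, _ = apc_ims_template.repeat_span
    t_pos = r0 + 3
    assert seq[t_pos] == "T"
    mutant = seq[:t_pos] + seq[t_pos + 1 :]
    events = classify_events(MutantRecord("t", mutant), apc_ims_template)
    assert len(events) == 1
    ev = events[0]
    assert ev.kind == KIND_INT_DEL
    assert ev.ref == "T"
    assert ev.detectable


def test_stop_creating_substitution_in_mononucleotide_run():
    """An A->T substitution creating an in-frame TAA stop within the repeat
    is a detectable interruption-substitution."""
    template = default_reporter_template("[A]_9", template_id="a9")
    seq = template.sequence
    r0, _ = template.repeat_span
    assert r0 % 3 == 0  # repeat starts on a codon boundary
    mutant = seq[:r0] + "T" + seq[r0 + 1 :]  # codon TAA
    events = classify_events(MutantRecord("t", mutant), template)
    assert [e.kind for e in events] == [KIND_INT_SUB]
    assert events[0].detectable


def test_silent_substitution_in_repeat_is_undetectable(gt10_template):
    seq = gt10_template.sequence
    r0, r1 = gt10_template.repeat_span
    pos = r0 + 5
    replacement = "A" if seq[pos] != "A" else "C"
    mutant = seq[:pos] + replacement + seq[pos + 1 :]
    events = classify_events(MutantRecord("t", mutant), gt10_template)
    assert [e.kind for e in events] == [KIND_INT_SUB]
    if not events[0].detectable:
        # no stop created: kept for spectra, excluded from EF numerators
        assert events[0].kind == KIND_INT_SUB


def test_coding_region_event_outside_repeat(gt10_template):
    seq = gt10_template.sequence
    mutant = "T" + seq[1:]  # ATG -> TTG start-codon change, amino acid change
    events = classify_events(MutantRecord("t", mutant), gt10_template)
    assert [e.kind for e in events] == [KIND_CODING]
    assert events[0].detectable


def test_indel_right_shift_is_canonical(gt10_template):
    """Deleting the first or the last unit of a perfect repeat yields the
    same mutant; events must land at the 3' end either way."""
    seq = gt10_template.sequence
    r0, r1 = gt10_template.repeat_span
    del_first = seq[:r0] + seq[r0 + 2 :]
    del_last = seq[: r1 - 2] + seq[r1:]
    assert del_first == del_last
    events = classify_events(MutantRecord("t", del_first), gt10_template)
    assert events[0].position == r1 - 2


def test_tandem_and_nontandem_grouping(gt10_template):
    seq = gt10_template.sequence
    r0, r1 = gt10_template.repeat_span
    # two adjacent substitutions (tandem) and one far-away substitution
    p1, p2, p3 = r0 + 4, r0 + 5, r1 - 3
    mutant = list(seq)
    for p in (p1, p2, p3):
        mutant[p] = "A" if seq[p] != "A" else "C"
    events = classify_events(MutantRecord("t", "".join(mutant)), gt10_template)
    groups = {}
    for ev in events:
        groups.setdefault(ev.tandem_group_id, []).append(ev.position)
    assert len(groups) == 2
    sizes = sorted(len(v) for v in groups.values())
    assert sizes == [1, 2]


def test_roundtrip_on_random_multi_event_mutants(gt10_template):
    rng = np.random.default_rng(8)
    seq = gt10_template.sequence
    r0, r1 = gt10_template.repeat_span
    for _ in range(25):
        mutant = seq
        # plant 1-2 well-separated edits
        pos = int(rng.integers(r0 + 2, r1 - 4))
        mutant = mutant[:pos] + mutant[pos + 1 :]  # deletion
        if rng.random() < 0.5:
            mutant = "G" + mutant[1:] if mutant[0] != "G" else "C" + mutant[1:]
        rec = MutantRecord("t", mutant)
        events = classify_events(rec, gt10_template)
        assert apply_events(seq, events) == mutant
        # determinism and order invariance of classification
        again = classify_events(MutantRecord("t", mutant), gt10_template)
        assert again == events


# -- multiple-event correction -----------------------------------------------------


def _record_with_groups(n_groups: int) -> MutantRecord:
    rec = MutantRecord("t", "")
    rec.events = [
        MutationalEvent(
            position=10 * g, kind=KIND_INT_SUB, ref="G", alt="T",
            detectable=True, tandem_group_id=g,
        )
        for g in range(n_groups)
    ]
    return rec


def test_correction_identity_when_single_event_records():
    records = [_record_with_groups(1) for _ in range(10)]
    assert correct_multiple_events(3e-4, records) == pytest.approx(3e-4)


def test_correction_scales_with_nontandem_groups():
    # 10 records carrying 15 detectable nontandem groups -> factor 1.5
    records = [_record_with_groups(1) for _ in range(5)] + [
        _record_with_groups(2) for _ in range(5)
    ]
    assert correct_multiple_events(2e-4, records) == pytest.approx(3e-4)


def test_tandem_pair_counts_once():
    rec = MutantRecord("t", "")
    rec.events = [
        MutationalEvent(5, KIND_INT_SUB, "G", "T", True, tandem_group_id=0),
        MutationalEvent(6, KIND_INT_SUB, "T", "A", True, tandem_group_id=0),
    ]
    assert correct_multiple_events(1e-4, [rec]) == pytest.approx(1e-4)
    with pytest.raises(ValueError):
        correct_multiple_events(1e-4, [])


# -- class-specific error frequencies ----------------------------------------------


def _events(kind_counts: dict, detectable=True):
    events = []
    for kind, n in kind_counts.items():
        for i in range(n):
            events.append(
                MutationalEvent(i, kind, "G", "T", detectable=detectable)
            )
    return events


def test_event_class_ef_examples():
    events = _events({KIND_INT_DEL: 2, KIND_UNIT_INDEL: 72})
    # 2 interruption-removal events of 74 total, Pol EF_est 3.4e-4
    ef = event_class_ef(3.4e-4, events, KIND_INT_DEL)
    assert ef == pytest.approx(2 / 74 * 3.4e-4)
    assert ef == pytest.approx(9.19e-6, rel=1e-2)
    # all events in one class
    only = _events({KIND_UNIT_INDEL: 10})
    assert event_class_ef(5e-4, only, KIND_UNIT_INDEL) == pytest.approx(5e-4)


def test_class_efs_sum_to_pol_ef_est_over_exhaustive_classes():
    events = _events({KIND_INT_DEL: 3, KIND_INT_SUB: 5, KIND_UNIT_INDEL: 12})
    kinds = {e.kind for e in events}
    total = sum(event_class_ef(2.5e-4, events, k) for k in kinds)
    assert total == pytest.approx(2.5e-4)


def test_event_class_ef_requires_detectable_events():
    with pytest.raises(ValueError):
        event_class_ef(1e-4, _events({KIND_INT_SUB: 3}, detectable=False),
                       KIND_INT_SUB)


# -- spectra and end-to-end summary -------------------------------------------------


def test_spectrum_report_trivial_cases(gt10_template):
    counts, records, truth = gen_mutant_collection(
        gt10_template, {"unit-deletion": 1.0}, n_mutants=10, rng_seed=0
    )
    for rec in records:
        classify_events(rec, gt10_template)
    report = spectrum_report(records)
    assert report["n_interruption_events"] == 0
    assert report["multi_interruption_fraction"] == 0.0
    assert sum(report["proportions"].values()) == 0.0

    counts, records, _ = gen_mutant_collection(
        gt10_template, {"interruption-substitution": 1.0}, n_mutants=1, rng_seed=1
    )
    for rec in records:
        classify_events(rec, gt10_template)
    report = spectrum_report(records)
    assert report["proportions"]["substitution"] == 1.0


def test_summary_conservation_on_synthetic_collection(gt10_template):
    spectrum = {
        "unit-deletion": 0.4,
        "unit-insertion": 0.1,
        "interruption-substitution": 0.3,
        "interruption-deletion": 0.15,
        "interruption-insertion": 0.05,
    }
    counts, records, truth = gen_mutant_collection(
        gt10_template, spectrum, n_mutants=200, rng_seed=5,
        mf_triple=(5e-4, 1e-4, 1e-4),
    )
    summary = summarize(
        counts["reaction"], counts["background"], counts["outside"],
        records, gt10_template,
    )
    assert summary.pol_ef == pytest.approx(3e-4)
    assert summary.n_events == 200
    assert sum(summary.class_efs.values()) == pytest.approx(summary.pol_ef_est)
    # planted interruption proportions are recovered exactly
    props = summary.spectrum["proportions"]
    assert props["substitution"] == pytest.approx(0.3 / 0.5)
    assert props["deletion"] == pytest.approx(0.15 / 0.5)
    assert props["insertion"] == pytest.approx(0.05 / 0.5)
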