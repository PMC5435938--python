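import random

import numpy as np
import pytest

from mzview import indexer, query
from mzview.errors import ContradictionWarning, PrecursorCycleError, ScanNotFoundError
from mzview.model import FilterCriteria
from mzview.synth import SynthConfig, corrupt, generate_run


def brute_force(headers, criteria: FilterCriteria):
    """Independent re-statement of the filter semantics."""
    out = []
    for h in headers:
        if criteria.ms_level is not None and h.ms_level != criteria.ms_level:
            continue
        rt = h.retention_time_s
        if criteria.rt_min_s is not None and rt < criteria.rt_min_s:
            continue
        if criteria.rt_max_s is not None and rt > criteria.rt_max_s:
            continue
        if criteria.mz_target is not None:
            if criteria.mz_field == "base_peak":
                value = h.base_peak_mz
            else:
                value = h.precursor.selected_ion_mz if h.precursor else None
            if value is None or abs(value - criteria.mz_target) > criteria.mz_tolerance:
                continue
        out.append(h)
    return out


def random_criteria(rng: random.Random, headers) -> FilterCriteria:
    kwargs = {}
    if rng.random() < 0.6:
        anchor = rng.choice(headers)
        field = rng.choice(["base_peak", "selected_ion"])
        base = (
            anchor.base_peak_mz
            if field == "base_peak"
            else (anchor.precursor.selected_ion_mz if anchor.precursor else None)
        )
        if base is None:
            base = rng.uniform(100, 1000)
        kwargs["mz_target"] = base + rng.uniform(-1.0, 1.0)
        kwargs["mz_field"] = field
        kwargs["mz_tolerance"] = rng.choice([0.01, 0.1, 0.5, 2.0])
    if rng.random() < 0.6:
        rts = sorted(h.retention_time_s for h in headers)
        a, b = sorted((rng.choice(rts), rng.choice(rts)))
        if rng.random() < 0.5:
            kwargs["rt_min_s"] = a
        kwargs["rt_max_s"] = b
    if rng.random() < 0.4:
        kwargs["ms_level"] = rng.choice([1, 2, 3, 4])
    return FilterCriteria(**kwargs)


class TestFilterScans:
    def test_no_criteria_returns_everything(self, index200_mzml):
        index, _ = index200_mzml
        assert query.filter_scans(index, FilterCriteria()) == index.headers

    def test_base_peak_target_matches_manifest(self, run200, index200_mzml):
        index, _ = index200_mzml
        truth = run200.manifest.scans[0]
        criteria = FilterCriteria(mz_target=truth.base_peak_mz, mz_tolerance=0.01)
        got = {h.scan_id for h in query.filter_scans(index, criteria)}
        expected = {
            s.mzml_id
            for s in run200.manifest.scans
            if s.base_peak_mz is not None
            and abs(s.base_peak_mz - truth.base_peak_mz) <= 0.01
        }
        assert got == expected
        assert truth.mzml_id in got

    def test_closed_rt_boundary_includes_exact_scan(self, index200_mzml):
        index, _ = index200_mzml
        h = index.headers[3]
        criteria = FilterCriteria(rt_min_s=h.retention_time_s, rt_max_s=h.retention_time_s)
        assert h in query.filter_scans(index, criteria)

    def test_selected_ion_with_ms1_is_contradictory(self, index200_mzml):
        index, _ = index200_mzml
        criteria = FilterCriteria(mz_target=500.0, mz_field="selected_ion", ms_level=1)
        with pytest.warns(ContradictionWarning):
            assert query.filter_scans(index, criteria) == []

    def test_scans_lacking_field_are_excluded_not_errors(self, index200_mzml):
        index, _ = index200_mzml
        criteria = FilterCriteria(mz_target=500.0, mz_field="selected_ion",
                                  mz_tolerance=1e9)
        got = query.filter_scans(index, criteria)
        assert all(h.precursor is not None for h in got)
        assert len(got) == sum(1 for h in index.headers if h.precursor is not None)

    def test_matches_brute_force_on_random_criteria(self, index200_mzml):
        index, _ = index200_mzml
        rng = random.Random(7)
        for _ in range(300):
            criteria = random_criteria(rng, index.headers)
            assert query.filter_scans(index, criteria) == brute_force(
                index.headers, criteria
            )

    def test_monotone_in_tolerance_and_window(self, index200_mzml):
        index, _ = index200_mzml
        rng = random.Random(13)
        for _ in range(100):
            c = random_criteria(rng, index.headers)
            if c.mz_target is None:
                continue
            wide = set(
                h.scan_id for h in query.filter_scans(
                    index, FilterCriteria(
                        mz_target=c.mz_target, mz_field=c.mz_field,
                        mz_tolerance=c.mz_tolerance,
                        rt_min_s=c.rt_min_s, rt_max_s=c.rt_max_s,
                        ms_level=c.ms_level,
                    )
                )
            )
            tight = set(
                h.scan_id for h in query.filter_scans(
                    index, FilterCriteria(
                        mz_target=c.mz_target, mz_field=c.mz_field,
                        mz_tolerance=c.mz_tolerance / 10.0,
                        rt_min_s=c.rt_min_s, rt_max_s=c.rt_max_s,
                        ms_level=c.ms_level,
                    )
                )
            )
            assert tight <= wide

    def test_conjunction_equals_intersection(self, index200_mzml):
        index, _ = index200_mzml
        a = FilterCriteria(ms_level=2)
        b = FilterCriteria(rt_min_s=100.0, rt_max_s=300.0)
        both = FilterCriteria(ms_level=2, rt_min_s=100.0, rt_max_s=300.0)
        got = query.filter_scans(index, both)
        ids_a = [h.scan_id for h in query.filter_scans(index, a)]
        ids_b = set(h.scan_id for h in query.filter_scans(index, b))
        assert [h.scan_id for h in got] == [i for i in ids_a if i in ids_b]


class TestPrecursorChain:
    def test_ms3_chain_matches_manifest_lineage(self, run_small, index_small_mzml):
        index, _ = index_small_mzml
        for truth in run_small.manifest.scans:
            if truth.ms_level != 3:
                continue
            chain = query.precursor_chain(index, truth.mzml_id)
            assert [s.header.scan_id for s in chain] == [
                f"scan={n}" for n in truth.lineage
            ]
            assert len(chain) == truth.ms_level - 1

    def test_ms1_has_empty_chain(self, run_small, index_small_mzml):
        index, _ = index_small_mzml
        ms1 = next(s for s in run_small.manifest.scans if s.ms_level == 1)
        assert query.precursor_chain(index, ms1.mzml_id) == []

    def test_inferred_parents_recover_lineage(self, run_noref):
        # no explicit spectrumRef/precursorScanNum in the file
        assert b"spectrumRef" not in run_noref.mzml_path.read_bytes()
        index, _ = indexer.build_index(run_noref.mzml_path)
        for truth in run_noref.manifest.scans:
            if truth.ms_level < 2:
                continue
            entry = index.get(truth.mzml_id)
            assert entry.header.precursor.parent_inferred
            chain = query.precursor_chain(index, truth.mzml_id)
            assert [s.header.scan_id for s in chain] == [
                f"scan={n}" for n in truth.lineage
            ]

    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_cycle_raises(self, tmp_path, which):
        run = generate_run(
            SynthConfig(n_ms1=2, msn_per_ms1=((2, 2),), seed=4), tmp_path
        )
        path = run.mzml_path if which == "mzml" else run.mzxml_path
        bad = corrupt(path, "cycle_precursors")
        index, _ = indexer.build_index(bad)
        cyclic = [
            e.scan_id for e in index.entries
            if e.header.precursor is not None
        ]
        with pytest.raises(PrecursorCycleError) as exc_info:
            query.precursor_chain(index, cyclic[0])
        assert exc_info.value.scan_id is not None

    def test_chain_bounded_by_max_ms_level(self, index_small_mzml):
        index, _ = index_small_mzml
        max_level = max(h.ms_level for h in index.headers)
        for sid in index.scan_ids:
            assert len(query.precursor_chain(index, sid)) <= max_level - 1

    def test_unknown_scan(self, index_small_mzml):
        index, _ = index_small_mzml
        with pytest.raises(ScanNotFoundError):
            query.precursor_chain(index, "nope")


class TestChromatograms:
    def test_mzml_file_declared_trace_matches_manifest(self, run_small,
                                                       index_small_mzml):
        index, _ = index_small_mzml
        chroms = query.get_chromatograms(index)
        assert len(chroms) == 1
        c = chroms[0]
        assert c.kind == "file_declared"
        assert c.time_s.tolist() == run_small.manifest.chromatogram_time_s
        assert c.intensity.tolist() == run_small.manifest.chromatogram_intensity

    def test_mzxml_synthesizes_ms1_tic(self, run_small, index_small_mzxml):
        index, _ = index_small_mzxml
        chroms = query.get_chromatograms(index)
        assert len(chroms) == 1
        c = chroms[0]
        assert c.kind == "tic"
        ms1 = [s for s in run_small.manifest.scans if s.ms_level == 1]
        assert c.time_s.tolist() == [s.rt_s for s in ms1]
        assert c.intensity.tolist() == [s.tic for s in ms1]

    def test_mzml_without_chromatogram_list_synthesizes_tic(self, tmp_path):
        run = generate_run(
            SynthConfig(n_ms1=3, msn_per_ms1=((2, 1),), seed=2,
                        write_chromatogram=False),
            tmp_path,
        )
        index, _ = indexer.build_index(run.mzml_path)
        chroms = query.get_chromatograms(index)
        assert len(chroms) == 1
        assert chroms[0].kind == "tic"
        assert len(chroms[0]) == 3  # MS1 scans only

    def test_empty_run_gives_empty_trace(self, run_empty):
        index, _ = indexer.build_index(run_empty.mzxml_path)
        chroms = query.get_chromatograms(index)
        assert len(chroms) == 1
        assert len(chroms[0]) == 0

    def test_times_are_seconds_and_sorted(self, index_small_mzml):
        index, _ = index_small_mzml
        for c in query.get_chromatograms(index):
            assert np.all(np.diff(c.time_s) >= 0)
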