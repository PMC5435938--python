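import builtins
import warnings

import numpy as np
import pytest
import refreader

from mzview import indexer
from mzview.errors import (
    CorruptScanError,
    DialectWarning,
    FormatParseError,
    IndexIncompleteError,
    ScanNotFoundError,
    UnsupportedFormatError,
)
from mzview.model import SourceFormat
from mzview.synth import SynthConfig, corrupt, generate_run


class TestDetectFormat:
    def test_indexed_mzml(self, run_small):
        assert indexer.detect_format(run_small.mzml_path) is SourceFormat.INDEXED_MZML

    def test_plain_mzml(self, tmp_path):
        run = generate_run(
            SynthConfig(n_ms1=1, msn_per_ms1=(), seed=0, wrap_indexed=False), tmp_path
        )
        assert indexer.detect_format(run.mzml_path) is SourceFormat.MZML

    def test_mzxml(self, run_small):
        assert indexer.detect_format(run_small.mzxml_path) is SourceFormat.MZXML

    def test_fasta_is_unsupported(self, tmp_path):
        fasta = tmp_path / "seqs.fa"
        fasta.write_text(">chr1\nACGTACGT\n")
        with pytest.raises((UnsupportedFormatError, FormatParseError)):
            indexer.detect_format(fasta)

    def test_wrong_xml_root_names_the_root(self, tmp_path):
        doc = tmp_path / "other.xml"
        doc.write_text('<?xml version="1.0"?>\n<!-- hi -->\n<sbml level="3"/>')
        with pytest.raises(UnsupportedFormatError) as exc_info:
            indexer.detect_format(doc)
        assert exc_info.value.root == "sbml"

    def test_extension_is_ignored(self, tmp_path, run_small):
        disguised = tmp_path / "actually_mzxml.mzML"
        disguised.write_bytes(run_small.mzxml_path.read_bytes())
        assert indexer.detect_format(disguised) is SourceFormat.MZXML


class TestBuildIndex:
    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_headers_match_manifest(self, run_small, which):
        path = run_small.mzml_path if which == "mzml" else run_small.mzxml_path
        index, metadata = indexer.build_index(path)
        manifest = run_small.manifest
        assert len(index) == manifest.spectrum_count == metadata.spectrum_count
        for entry, truth in zip(index.entries, manifest.scans):
            h = entry.header
            expected_id = truth.mzml_id if which == "mzml" else str(truth.num)
            assert h.scan_id == expected_id
            assert h.ms_level == truth.ms_level
            assert h.retention_time_s == truth.rt_s
            assert h.base_peak_mz == truth.base_peak_mz
            assert h.base_peak_intensity == truth.base_peak_intensity
            assert h.total_ion_current == truth.tic
            if truth.parent_num is None:
                assert h.precursor is None
            else:
                expected_parent = (
                    f"scan={truth.parent_num}" if which == "mzml" else str(truth.parent_num)
                )
                assert h.precursor.parent_scan_id == expected_parent
                assert h.precursor.selected_ion_mz == truth.selected_ion_mz

    def test_empty_run(self, run_empty):
        for path in (run_empty.mzml_path, run_empty.mzxml_path):
            index, metadata = indexer.build_index(path)
            assert len(index) == 0
            assert metadata.spectrum_count == 0

    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_completeness_against_text_scan(self, run200, which):
        path = run200.mzml_path if which == "mzml" else run200.mzxml_path
        index, _ = indexer.build_index(path)
        assert len(index) == refreader.count_scan_elements(path)

    def test_mzml_spans_tile_without_overlap(self, index200_mzml, run200):
        index, _ = index200_mzml
        spans = [(e.byte_start, e.byte_end) for e in index.entries]
        assert spans == sorted(spans)
        for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
            assert end_a <= start_b
        assert all(0 <= a < b <= index.file_size for a, b in spans)

    def test_mzxml_sibling_spans_nest_or_tile(self, index200_mzxml):
        index, _ = index200_mzxml
        by_id = {e.scan_id: e for e in index.entries}
        for entry in index.entries:
            pre = entry.header.precursor
            if pre is not None and pre.parent_scan_id in by_id:
                parent = by_id[pre.parent_scan_id]
                # child span strictly inside parent span (mzXML nesting)
                assert parent.byte_start < entry.byte_start
                assert entry.byte_end < parent.byte_end
        roots = [e for e in index.entries if e.header.ms_level == 1]
        spans = [(e.byte_start, e.byte_end) for e in roots]
        for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
            assert end_a <= start_b

    def test_single_monotone_pass(self, run200, monkeypatch):
        reads = []
        real_open = builtins.open
        target = str(run200.mzml_path)

        class Tracking:
            def __init__(self, fh):
                self._fh = fh

            def read(self, n=-1):
                reads.append(self._fh.tell())
                return self._fh.read(n)

            def __getattr__(self, name):
                return getattr(self._fh, name)

            def __enter__(self):
                return self

            def __exit__(self, *a):
                self._fh.close()

        def counting_open(path, mode="r", *args, **kwargs):
            fh = real_open(path, mode, *args, **kwargs)
            if "b" in mode and str(path) == target:
                return Tracking(fh)
            return fh

        monkeypatch.setattr(builtins, "open", counting_open)
        indexer.build_index(run200.mzml_path)
        assert reads == sorted(reads)
        assert len(reads) > 1  # actually chunked


class TestFetchSpectrum:
    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_every_fetch_equals_full_parse(self, run200, index200_mzml,
                                           index200_mzxml, which):
        if which == "mzml":
            index, _ = index200_mzml
            reference = refreader.read_mzml(run200.mzml_path)
            ids = [r["id"] for r in reference]
        else:
            index, _ = index200_mzxml
            reference = refreader.read_mzxml(run200.mzxml_path)
            ids = [r["num"] for r in reference]
        assert len(reference) == len(index)
        for ref, scan_id in zip(reference, ids):
            spec = indexer.fetch_spectrum(index, scan_id)
            assert spec.header.scan_id == scan_id
            assert spec.peaks.mz.tolist() == ref["mz"]  # bit-exact (f64)
            assert spec.peaks.intensity.tolist() == ref["intensity"]

    def test_unknown_scan_lists_near_matches(self, index_small_mzml):
        index, _ = index_small_mzml
        with pytest.raises(ScanNotFoundError) as exc_info:
            indexer.fetch_spectrum(index, "scan=9999")
        assert exc_info.value.suggestions
        assert all(s in index for s in exc_info.value.suggestions)

    def test_repeated_fetches_are_independent(self, index_small_mzml):
        index, _ = index_small_mzml
        sid = index.scan_ids[0]
        a = indexer.fetch_spectrum(index, sid)
        b = indexer.fetch_spectrum(index, sid)
        assert a.peaks == b.peaks

    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_bytes_read_bounded_by_span(self, run200, index200_mzml,
                                        index200_mzxml, which):
        index, _ = (index200_mzml if which == "mzml" else index200_mzxml)
        path = run200.mzml_path if which == "mzml" else run200.mzxml_path

        class Counting:
            def __init__(self, fh):
                self.fh = fh
                self.bytes_read = 0

            def seek(self, *a):
                return self.fh.seek(*a)

            def read(self, n=-1):
                data = self.fh.read(n)
                self.bytes_read += len(data)
                return data

        fixed_overhead = 4096
        with open(path, "rb") as fh:
            for entry in index.entries:
                counter = Counting(fh)
                indexer.fetch_spectrum(index, entry.scan_id, fileobj=counter)
                span = entry.byte_end - entry.byte_start
                assert counter.bytes_read <= span + fixed_overhead
                assert counter.bytes_read <= index.file_size / 10


class TestRobustness:
    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_truncated_file_carries_partial_index(self, tmp_path, which):
        run = generate_run(
            SynthConfig(n_ms1=3, msn_per_ms1=((2, 1),), seed=3), tmp_path
        )
        path = run.mzml_path if which == "mzml" else run.mzxml_path
        bad = corrupt(path, "truncate")
        with pytest.raises(IndexIncompleteError) as exc_info:
            indexer.build_index(bad)
        partial = exc_info.value.partial_index
        assert partial is not None
        assert 0 < len(partial) < run.manifest.spectrum_count

    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_bad_offset_table_falls_back_with_warning(self, tmp_path, which):
        run = generate_run(
            SynthConfig(n_ms1=3, msn_per_ms1=((2, 1),), seed=3), tmp_path
        )
        path = run.mzml_path if which == "mzml" else run.mzxml_path
        clean_index, _ = indexer.build_index(path)
        bad = corrupt(path, "bad_offsets")
        with pytest.warns(DialectWarning):
            bad_index, _ = indexer.build_index(bad)
        assert [(e.scan_id, e.byte_start, e.byte_end) for e in bad_index.entries] == [
            (e.scan_id, e.byte_start, e.byte_end) for e in clean_index.entries
        ]

    def test_clean_file_emits_no_dialect_warning(self, run_small):
        with warnings.catch_warnings():
            warnings.simplefilter("error", DialectWarning)
            indexer.build_index(run_small.mzml_path)
            indexer.build_index(run_small.mzxml_path)

    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_bad_base64_breaks_only_that_scan(self, tmp_path, which):
        run = generate_run(
            SynthConfig(n_ms1=3, msn_per_ms1=((2, 1),), seed=3), tmp_path
        )
        path = run.mzml_path if which == "mzml" else run.mzxml_path
        bad = corrupt(path, "bad_base64")
        index, _ = indexer.build_index(bad)
        failures = []
        for sid in index.scan_ids:
            try:
                indexer.fetch_spectrum(index, sid)
            except CorruptScanError as exc:
                assert exc.byte_start is not None
                failures.append(sid)
        assert len(failures) == 1


class TestSidecar:
    def test_round_trip(self, tmp_path, run_small):
        index, metadata = indexer.build_index(run_small.mzml_path)
        sc = indexer.save_sidecar(index, metadata, tmp_path / "idx.json")
        loaded = indexer.load_sidecar(run_small.mzml_path, sc)
        assert loaded is not None
        lindex, lmeta = loaded
        assert lindex.scan_ids == index.scan_ids
        assert [e.byte_start for e in lindex.entries] == [
            e.byte_start for e in index.entries
        ]
        assert lindex.entries[0].header == index.entries[0].header
        assert lmeta.spectrum_count == metadata.spectrum_count

    def test_stale_sidecar_is_rejected(self, tmp_path):
        run = generate_run(SynthConfig(n_ms1=1, msn_per_ms1=(), seed=0), tmp_path)
        index, metadata = indexer.build_index(run.mzml_path)
        sc = indexer.save_sidecar(index, metadata)
        # rewrite the source: size changes, sidecar must be considered stale
        run.mzml_path.write_bytes(run.mzml_path.read_bytes() + b"\n<!-- x -->\n")
        assert indexer.load_sidecar(run.mzml_path, sc) is None

    def test_open_run_uses_and_refreshes_sidecar(self, tmp_path):
        run = generate_run(SynthConfig(n_ms1=2, msn_per_ms1=(), seed=0), tmp_path)
        index1, _ = indexer.open_run(run.mzml_path, use_sidecar=True)
        assert indexer.sidecar_path(run.mzml_path).exists()
        index2, _ = indexer.open_run(run.mzml_path, use_sidecar=True)
        assert index2.scan_ids == index1.scan_ids


class TestRandomAccessEquivalence:
    @pytest.mark.parametrize("which", ["mzml", "mzxml"])
    def test_fetch_equals_iter(self, run_small, which):
        path = run_small.mzml_path if which == "mzml" else run_small.mzxml_path
        index, _ = indexer.build_index(path)
        streamed = list(indexer.iter_spectra(index))
        for entry, spec in zip(index.entries, streamed):
            direct = indexer.fetch_spectrum(index, entry.scan_id)
            assert np.array_equal(direct.peaks.mz, spec.peaks.mz)
            assert np.array_equal(direct.peaks.intensity, spec.peaks.intensity)
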