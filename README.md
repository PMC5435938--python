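# mzview

Lazy, index-based viewer for mzML / indexedmzML / mzXML mass-spectrometry
files. One streaming pass over the file records the byte span and header of
every scan; after that, any spectrum is fetched by seeking to its span and
reading only those bytes, so multi-GB files stay navigable one scan at a
time.

Features:

- **Format detection** from the document root (never the file extension).
- **Binary peak decoding**: 32/64-bit IEEE-754 floats, plain or
  zlib-compressed base64, little-endian separate arrays (mzML) and
  big-endian interleaved pairs (mzXML).
- **Scan headers** normalized at parse time (retention times always in
  seconds), with PSI-MS controlled-vocabulary annotation for mzML metadata
  from a bundled vocabulary snapshot (`src/mzview/data/psi_ms_terms.tsv`).
- **Search filters**: base-peak or selected-ion m/z with a tolerance window
  (default 0.5 Th), closed retention-time intervals, MS level.
- **Precursor chains**: MSn → … → MS1 traversal via explicit parent
  references, with a nearest-preceding-scan fallback when the file omits
  them; cycles are detected and reported.
- **Chromatograms**: mzML `chromatogramList` traces, or a synthesized TIC
  (MS1 scans only) when the file declares none / for mzXML.
- **Rendering**: stick spectrum plots with a summary block, optional
  chromatogram and precursor panels, top-N peak labels, and a JSON sidecar
  (`<figure>.labels.json`) recording panel count and placed labels.
- **Synthetic fixtures**: `mzview.synth` writes deterministic, twin
  mzML/mzXML runs with a ground-truth manifest, plus four corruption modes
  for error-path testing. No external data needed anywhere.

## CLI

```sh
# generate a fixture run to play with
mzview synth demo --seed 1 --n-ms1 10 --msn "2:2,3:1"

# file-level metadata, counts, MS-level histogram
mzview info demo/run.mzML

# filter scans (tab-separated with --tsv)
mzview list demo/run.mzML --mz 445.1 --tol 0.5 --rt-min 10 --rt-max 300 --tsv
mzview list demo/run.mzXML --ms-level 2 --mz-field selected_ion --mz 500

# render one scan with chromatogram + precursor panels and 5 peak labels
mzview show demo/run.mzML --scan "scan=4" --label-peaks 5 \
    --chromatogram --precursors --out fig.png
```

Exit codes: 0 success (including empty results), 2 bad usage, 3 unreadable
or unsupported input, 4 corrupt content. Default m/z tolerance can be set in
a TOML config passed via `--config` (`[mzview] mz_tolerance = 0.1`).

## Library

```python
from mzview import build_index, fetch_spectrum, filter_scans, FilterCriteria

index, metadata = build_index("run.mzML")
hits = filter_scans(index, FilterCriteria(mz_target=445.1, mz_tolerance=0.1))
spectrum = fetch_spectrum(index, hits[0].scan_id)
```

`open_run(path, use_sidecar=True)` persists the index as a JSON sidecar
keyed by file size + mtime, so reopening a large file skips the streaming
pass; stale sidecars are rebuilt silently.

## Layout

| module | role |
| --- | --- |
| `mzview.model` | domain types (peak lists, headers, index, criteria) |
| `mzview.codec` | base64/zlib/IEEE-754 array encode/decode, (de)interleave |
| `mzview.indexer` | format detection, streaming byte-offset index, random-access fetch, sidecar |
| `mzview.readers` | mzML/mzXML fragment parsing, CV annotation |
| `mzview.query` | filters, precursor chains, chromatograms |
| `mzview.render` | figures + label sidecars |
| `mzview.synth` | deterministic fixture generator + corruption modes |
| `mzview.cli` | `mzview` command-line tool |
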