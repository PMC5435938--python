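# Static accession -> preferred-name snapshot of the PSI-MS controlled
# vocabulary (plus the unit-ontology terms mzML uses), covering the terms
# this viewer reads or writes. Two tab-separated columns.
MS:1000016	scan start time
MS:1000031	instrument model
MS:1000040	m/z
MS:1000041	charge state
MS:1000042	peak intensity
MS:1000045	collision energy
MS:1000127	centroid spectrum
MS:1000128	profile spectrum
MS:1000129	negative scan
MS:1000130	positive scan
MS:1000133	collision-induced dissociation
MS:1000235	total ion current chromatogram
MS:1000285	total ion current
MS:1000465	scan polarity
MS:1000500	scan window upper limit
MS:1000501	scan window lower limit
MS:1000504	base peak m/z
MS:1000505	base peak intensity
MS:1000511	ms level
MS:1000512	filter string
MS:1000514	m/z array
MS:1000515	intensity array
MS:1000519	32-bit integer
MS:1000521	32-bit float
MS:1000522	64-bit integer
MS:1000523	64-bit float
MS:1000527	highest observed m/z
MS:1000528	lowest observed m/z
MS:1000529	instrument serial number
MS:1000530	file format conversion
MS:1000544	Conversion to mzML
MS:1000560	mass spectrometer file format
MS:1000574	zlib compression
MS:1000576	no compression
MS:1000579	MS1 spectrum
MS:1000580	MSn spectrum
MS:1000584	mzML format
MS:1000595	time array
MS:1000744	selected ion m/z
MS:1000776	scan number only nativeID format
MS:1000796	spectrum title
MS:1000827	isolation window target m/z
MS:1000828	isolation window lower offset
MS:1000829	isolation window upper offset
UO:0000010	second
UO:0000028	millisecond
UO:0000031	minute
UO:0000169	parts per million
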