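# Methods

## The processing model

`fiebin` processes flow-infusion electrospray HRMS fingerprinting data
under three assumptions: (i) there is no chromatography, so a feature is
an m/z interval, not a retention-time peak; (ii) within the plug-flow
region of the infusion the composition reaching the source is stable,
so scans there are replicate measurements that can be averaged; and
(iii) instrument m/z drift between scans is small relative to the
coarse bin width, so a coarse bin collects all scan-level appearances
of one ion, and the modal fine (0.00001 amu) m/z of those appearances
recovers the ion's accurate mass.

The pipeline is deterministic and purely arithmetical: no peak-shape
model, no fitting, no imputation. Its stages and their exact rules are
listed in the README; this note records the decisions behind them.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| coarse bin width `w` | 0.01 | amu | best trade-off between bin purity and feature resolution for Orbitrap-class resolving power; 1, 0.1, 0.001, 0.0001 supported for comparison |
| plug-flow fraction | 0.5 | of max TIC | scans above half the maximal TIC sit on the stable part of the infusion bolus |
| occupancy threshold | 2/3 | proportion | the conventional "66%" missing-value rule, interpreted as the exact fraction 2/3 with a strict `>` comparison |
| QC RSD threshold | 50 | % | infusion ionisation is less reproducible than LC-MS (20%) or GC-MS (30%); comparison is strict `<` on the n−1 standard deviation |
| match tolerance | 10 | ppm | generous envelope around the instrument's ~3 ppm accuracy so true products are not missed |
| match occupancy | 1.0 | proportion | only consensus features detected in every injection are trustworthy identification anchors |

## Numerical choices

* **Grid assignment** is round-half-away-from-zero at both the 5- and
  the coarse-decimal precision, computed in decimal-scaled integer
  arithmetic: a fine bin is the integer `round(mz · 1e5)` (evaluated on
  the float's shortest decimal representation, so 133.015 → 13301500
  regardless of its binary representation), and coarse keys derive from
  fine keys by exact integer rounding. Bin identity is the
  (polarity, integer grid index) pair — never a float — and bin names
  (`n133.01`) are formatted from the integer, so labels are stable
  across platforms. Banker's rounding is deliberately avoided.
* **Window averaging** divides by the number of window scans, counting
  scans where a bin is absent as zero rather than averaging over
  present scans only. This preserves total ion count through the
  pipeline (per scan, coarse totals = fine totals = TIC to 1e-9
  relative) and penalises intermittently detected bins.
* **Modal accurate m/z** uses the occurrence count pooled over the
  whole sample set; ties break by larger total abundance, then by
  smaller m/z, so the assignment is deterministic. Pooling gives a
  single consensus value per bin, which is what adduct matching
  consumes.
* **Single-scan removal** is a set-level filter applied before window
  averaging, and counts occurrences within the plug-flow window only —
  those are the only scans processed downstream, so an event outside
  the window could never contribute signal anyway.
* **Purity/centrality** are computed per sample from all fine-bin
  occurrences across the window, then averaged (unweighted) over the
  samples in which the bin was detected. A bin whose members all share
  one m/z takes the exact path `ē = 0`, so `p = 1` holds exactly. Both
  scores are clamped to [0, 1] with a warning if members fall outside
  the window (impossible for grid-assigned bins; defensive for direct
  calls).
* **Electron mass** (0.000549 Da) is folded into every adduct delta —
  subtracted per positive charge, added per negative — because at
  100,000 resolving power it exceeds the ppm-level accuracy of low-m/z
  ions. `[M+41K]1+` and `[M+37Cl]1−` use the minor-isotope masses
  40.96182526 and 36.96590259. Atomic masses are a versioned constant
  table (IUPAC/CIAAW 2021 monoisotopic values, ≥ 6 dp, C = 12 exactly);
  one published reference value (p-cresol sulfate [M−H]1−, 187.0070)
  differs from this table's result (187.0071) by one unit in the last
  place, evidently reflecting an older constant set, and is therefore
  checked only to ±0.0001 Da.
* **ppm error** is reported signed, `1e6 (measured − theoretical) /
  theoretical`; matching uses its absolute value.

## Design choices where the design was open

* **Cycle ordinals.** When a run interleaves several scan filters, scans
  are indexed by their rank within their own filter, so per-filter TIC
  traces align and can be averaged into one infusion profile. Vendor
  scan numbers are ignored; only ordinal position along the infusion
  matters. With unequal per-filter scan counts, the averaged profile at
  each position is the mean over the traces that reach it.
* **Window detection** is pooled over all replicate injections by
  default (one window per sample set); a per-sample mode is available
  (`per_sample_window=True`, `--per-sample-window`). The cutoff
  comparison is strict (`>`), ties at exactly half the maximum are
  excluded, and of several disjoint supra-threshold regions only the one
  containing the (earliest) global maximum is kept — the plug flow is a
  single injection bolus.
* **Polarities** are processed fully independently end to end; a
  positive and a negative bin never pool, even at the same grid index.
* **Missing cells** are 0, not NaN; occupancy is the proportion of
  samples with a cell > 0. Imputation is out of scope.
* **Filter order.** Occupancy and QC-RSD filters are both column-wise
  predicates, so they commute; the recommended order is therefore
  immaterial and both orders are tested.
* **mzML I/O** is implemented directly on lxml: a reader for centroided
  MS1 spectra (polarity, scan window, 32/64-bit float arrays, zlib) and
  a writer emitting uncompressed 64-bit little-endian arrays with the
  standard controlled-vocabulary terms. Profile-mode spectra and spectra
  without polarity metadata are hard errors. mzXML is read-only
  convenience. Read-back is cross-checked in the test suite against
  Bioconductor's mzR as an independent oracle.

## The synthetic generator

`fiebin.simulate` emulates exactly the features of real acquisitions
the method depends on: a trapezoid TIC envelope (7-scan rise, 10-scan
plateau, 11-scan fall within 32 scans per filter — odd rise/fall so no
scan sits exactly at half maximum and the analytic supra-half window is
unambiguous), two polarities × two overlapping acquisition ranges
(55–280, 270–1200 m/z), multiplicative per-scan m/z jitter (default
2 ppm, matching Orbitrap calibration drift; an additive-Da mode exists
for grid edge-case tests), 10% between-scan abundance variation, and
Poisson single-scan noise peaks (mean 2 per scan) with abundances drawn
log-uniformly over the two decades below the smallest compound
abundance so noise cannot perturb plug-flow detection. The default
compound list is 20 common metabolites whose "true" m/z are the exact
[M+H]1+ / [M−H]1− theoretical values from their formulas, so end-to-end
runs can be matched back against predicted ionisation products.

It deliberately does **not** simulate isotopologue patterns, in-source
fragmentation, adduct multiplicity per compound, detector saturation,
or inter-batch drift. Passing tests therefore demonstrate that the
*processing arithmetic* is correct under realistic scan structure and
noise — not that the method resolves isotope clusters or survives
batch effects in real biological matrices.

Default problem sizes (10 injections × 4 filters × 32 scans, 20
compounds) keep a full pipeline run under a second while exercising
every stage; they mirror the replicate structure of a typical
standards-mix experiment at reduced scan count.

## Known limitations

* A compound whose m/z sits near a coarse-grid boundary (e.g. alanine
  [M+H]1+ at 90.05495 on the 0.01 grid) splits between two bins under
  ppm jitter; both halves carry accurate m/z near truth, but abundance
  divides between them. This is inherent to fixed-grid binning — the
  centrality metric exists precisely to flag such bins.
* Accurate-m/z consensus assumes drift is centred on the true m/z; a
  systematic calibration offset propagates into every accurate m/z.
* The single-scan filter only removes strictly single-occurrence bins;
  noise recurring by chance (two events in one coarse bin anywhere in
  the set) survives to the occupancy/RSD filters.
* mzML support covers centroided MS1 spectra as produced by msconvert;
  chromatogram lists, MSn and vendor extensions are ignored.
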