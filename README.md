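# readstitch

Combined assembly correction, scaffolding and gap filling for draft genome
assemblies using long reads (PacBio CLR/HiFi or Oxford Nanopore).

Draft assemblies produced from short reads or low-coverage data are
fragmented: scaffolds contain N-gaps of poorly estimated length, contigs end
where repeats begin, and a fraction of joins are outright wrong.  Given the
draft, the long reads, and two minimap2-style PAF alignments (reads against
the split assembly, and the split assembly against itself), `readstitch`

1. **splits** every scaffold into gap-free contigs at N-runs,
2. **corrects** misassemblies: positions where reads consistently stop
   following a contig while both read and contig continue are broken,
   support being weighed against spanning "veto" alignments,
3. **bridges** contig ends with read evidence and filters the bridge
   clusters three ways — a minimum count against chimeric reads, a
   one-sided exceedance test on remaining read lengths against alignments
   to the wrong repeat copy, and a negative-binomial coverage model against
   spurious rare connections,
4. **traverses** a scaffold graph built from reads spanning three or more
   scaffolds, resolving loops, inverted repeats and up-to-ploidy haplotype
   alternatives into final scaffold paths, and
5. **fills** every resulting gap with the best spanning read (anchor
   mapping qualities first, then gap length closest to the cluster mean,
   then matching bases), so that each junction is closed with real sequence
   in the same step that established it.

The output is an improved FASTA plus a change list (TSV, optionally AGP)
recording every kept segment, fill, break and drop — useful when annotations
must be lifted over.

## The statistics at the core

*Wrong-copy test.* For bridges sharing a contig end, the remaining read
lengths of the cluster with the longest reads act as control; every other
cluster is tested with the one-sided exceedance probability

P(≥ r of n_c controls exceed the test maximum) = C(n_c, r) / C(n_c + n_t, r),

computed exactly.  A truncated length distribution (reads stopping at a
repeat-copy boundary) yields a small p-value and the bridge is removed.

*Coverage model.* Original contigs are tiled with full-length bins at
read-length-quantile bin sizes; per bin size the lower half of the
cumulative distribution of per-bin read counts is fitted with a
negative-binomial CDF by least squares (the upper half would be contaminated
by collapsed repeats).  A bridge whose count is many times less probable
than a competitor's at the same end — compared on quality-cumulative counts,
lower anchor mapping quality first — is removed.

## Worked example

Everything below runs from synthetic fixtures generated by the package
itself; no external data or mapper is needed.

```
readstitch fixture clean-haploid --out-dir fx
readstitch run fx/draft.fasta fx/reads.fasta fx/reads.paf fx/self.paf --out-dir out
```

The run prints the stage report:

```json
{
  "alignments_in": 810,
  "alignments_accepted": 800,
  "break_details": [],
  "breaks": 0,
  "dropped_contigs": 0,
  "bridge_clusters": 12,
  "bridge_clusters_kept": 12,
  "scaffolds_unconflicted": 1,
  "long_range_connections": 0,
  "final_paths": 1,
  "junctions": 12,
  "junctions_filled": 12
}
```

Here the 200 kb single-chromosome fixture (13 contigs, 10 N-gaps and 2
scaffold breaks) yields 12 junctions; every one is bridged and filled with a
read, producing a single output scaffold (`out/improved.fasta`) that is an
exact substring of the true genome.  `readstitch evaluate chimera` scores a
misassembled fixture against its truth and additionally reports
`breaks_found: 2, breaks_spurious: 0, identity: 1.0` — both injected
chimeric joins are found, broken and correctly re-scaffolded.

The library surface mirrors the pipeline: `split_assembly`, `form_bridges`,
`cluster_bridges`, `exceedance_pvalue`, `fit_coverage_model`,
`filter_bridges`, `scaffold_unconflicted`, `build_graph`, `traverse_graph`,
`select_gap_reads`, `apply_changes` — see `docs/methods.md` for the model
details and parameter defaults.

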