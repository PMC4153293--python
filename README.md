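# dnralink

Links the **structure** of sediment DNRA communities (dissimilatory nitrate
reduction to ammonium — the nitrate respiration pathway that recycles
NO₃⁻ to NH₄⁺ instead of removing nitrogen as N₂) to their **activity**.
It is built for microbial ecologists analysing functional-gene amplicon
surveys of the *nrfA* gene (the pentaheme cytochrome c nitrite reductase
marker for DNRA bacteria) alongside ¹⁵N tracer incubations, the design used
in estuarine salinity-gradient studies: five sediment sites, barcoded
Ion-Torrent *nrfA* amplicons, and slurry incubations spiked with ¹⁵NO₃⁻.

The pipeline covers:

* **Tracer rates** — potential DNRA rate from label accumulation in the
  extractable ammonium pool, `rate = MF₁₅NH₄ · [NH₄] / (MF₁₅NO₃ · t)` with
  carrier-ammonium correction, as a single-endpoint estimator and an OLS
  regression over the time series (in nmol N g⁻¹ h⁻¹).
* **Read processing** — barcode demultiplexing, IUPAC primer trimming,
  length/mean-Q25 filtering, homopolymer denoising, a half-split bimera
  screen, frame-aware translation against NrfA references, dereplication.
* **Alpha diversity** — Kimura-corrected protein distances
  d = −ln(1 − p − 0.2p²), furthest-neighbour OTUs at the 0.1 sub-genus
  cutoff (calibrated on a labelled reference pool), Chao1, ACE, Shannon H,
  Pielou's J = H/ln(S), analytic rarefaction.
* **Beta diversity** — cross-site >90%-identity OTU table, the
  dominant (>1%) / low-abundance / rare (≤0.1%) partition with
  endemic/cosmopolitan flags, neighbour-joining trees with bootstrap
  support, weighted normalized UniFrac, PCoA, heat-map export.
* **Statistics** — Pearson correlations (two-tailed t), one-way ANOVA,
  canonical correspondence analysis (CCA), and a report reproducing the
  five-site study's headline numbers from its printed tables.
* **Synthetic data** — a seeded generator for every input (reference pools,
  site communities, error-bearing FASTQ with a truth sidecar, tracer series,
  geochemistry tables) so the whole pipeline is testable offline with known
  ground truth.

## Worked example

```python
from dnralink import synthetic_data as syn, read_processing as rp
from dnralink import community_structure as cs, isotope_rates as ir

pool = syn.generate_reference_pool(12, 3, length=80, seed=3,
                                   r_within=0.08, r_between=0.4)
config = syn.SimulationConfig(n_sites=3, depth_per_site=400, seed=3)
communities = syn.generate_site_communities(pool, config)
syn.simulate_reads(communities, pool, config, "reads.fastq", "truth.tsv")

refs = {e.id: e.protein for e in pool.entries}
barcodes = syn.default_barcodes([c.site_id for c in communities])
libraries, stats, _ = rp.process_reads("reads.fastq", barcodes, refs)
print(stats.input, stats.quality_passed, stats.valid)
# 1200 1084 988          <- reads surviving each filtering stage

table = cs.cluster_cross_site(libraries)           # >90% identity OTUs
classes = cs.classify_abundance(table)
print(cs.endemic_and_dominant_percentages(table, classes))
#          pct_dominant  pct_endemic
# site_id
# S1               95.4         25.2
# S2               96.0          8.6
# S3               93.1         58.8

series = syn.simulate_tracer_series(true_rate=20.0, nh4_pool=500.0,
                                    noise_sd=0.0)
print(ir.dnra_rate_regression(series).rate)        # 20.0 nmol N g^-1 h^-1
```

`pct_dominant` is the share of a site's valid sequences held by OTUs that
each exceed 1% of that site's community; `pct_endemic` the share held by
OTUs seen at that site only.  Both track the simulator's ground truth
(here within ~3 percentage points at only 400 reads per site), and the
noiseless tracer series inverts exactly to its true rate.

The packaged study tables reproduce the headline statistics of the original
five-site survey, e.g. Pearson r = −0.94 between extractable NH₄⁺ and
Shannon diversity, and r = 0.92 between dominant-sequence percentage and
DNRA rate:

```python
from dnralink import stats_link as sl
report = sl.build_report(sl.load_study_tables())
print(report["headline_checks"])   # all seven checks pass
```

A thin CLI mirrors these steps: `dnralink simulate`, `dnralink process`,
`dnralink rates`, `dnralink link`.

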