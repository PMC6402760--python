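# utrlens

Sequence-level characterization of 5′/3′ UTR variant catalogs.

Untranslated regions decide much of a transcript's post-transcriptional
fate: upstream AUGs and upstream ORFs (uORFs) repress initiation at the main
start codon, polyadenylation signals (PAS) position the 3′ end and set
cleavage efficiency, miRNAs silence transcripts through accessible 3′ UTR
sites, and the repertoire of secondary structures a UTR can adopt constrains
which regulatory elements can form.  Gene families with alternative UTR
variants — the motivating case is the mammalian Lipocalins, whose
early-diverging members (APOD, RBP4, PTGDS, APOM) carry long, uORF-laden,
conserved leaders while late-diverging members (LCN2, ORM2, …) carry short
permissive ones — need all of these features extracted per variant and
compared across species.

`utrlens` packages that analysis as a reusable pipeline over FASTA catalogs
keyed by `gene|variant|species`:

* **composition** — length, G+C (Ns excluded), codon-position-partitioned
  G+C, and the Pearson/OLS correlation of UTR vs third-codon-position G+C
  with a 95% confidence band;
* **uorf_scan** — every uAUG and uORF, with Kozak context at −3/+4
  (optimal / adequate / weak), cap distance classes (>19 nt optimal,
  <12 nt weak), `O`/`W` summary strings such as `O2/W1`, and a documented
  surrogate rule mapping a profile to translation class I (low) or III
  (efficient);
* **pas_scan** — AAUAAA (C), AUUAAA (NC) and rarer variant hexamers (NC\*),
  typed and classified VE/E/LE by a 10–45 nt distance-to-end window, plus
  alternative 3′-end candidates implied by usable signals;
* **kmer_enrichment** — over-represented 6–8-mers against a Markov
  background (order 0–2, trained on the input set), upper-tail binomial
  p-values and a −log₁₀ E-value significance index, with two-strand
  (reverse-complement-pooled) counting;
* **mirna_accessibility** — seed matches (≥8 nt, one G:U and one mismatch
  allowed, position 1 strict) scored by ΔΔG = ΔG<sub>duplex</sub> −
  ΔG<sub>open</sub>; sites with ΔΔG < −10 kcal/mol are accessible, and very
  accessible when additionally ΔG<sub>open</sub> > −10 kcal/mol;
* **structure_shapes** — MFE and suboptimal structures within +5 kcal/mol,
  an abstract-shape census (helices collapse, branching survives), and MFE
  helices conserved in ≥60% of the suboptimal set;
* **conservation** — pairwise global-alignment identity (free end gaps,
  terminal overhangs excluded), codon-position-partitioned identity,
  identity matrices, ≥60% homology calls, and Nei–Gojobori (1986) Ka/Ks
  with exhaustive shortest-pathway averaging and Jukes–Cantor correction;
* **synthetic_data** — a planted-feature generator (uORFs with chosen
  contexts and cap distances, PAS at chosen distances, enriched k-mers,
  miRNA seed sites, ortholog families with third-codon-position-fast
  divergence) whose truth tables make every scanner testable end to end.

Folding and hybridization thermodynamics go through pluggable engine
contracts: a deterministic exhaustive toy engine (base-pair maximization,
−1 kcal/mol per pair) backs the tests, and ViennaRNA bindings are used when
available (`engine="vienna"`).

## Worked example

Generate an early-diverging-style synthetic catalog and run the pipeline:

```python
from utrlens.synthetic_data import ed_preset, write_outputs
from utrlens.pipeline import RunConfig, run_characterization

paths = write_outputs(ed_preset(42), "demo/sim")
config = RunConfig(utr5_fasta=str(paths["utr5"]), utr3_fasta=str(paths["utr3"]),
                   cds_fasta=str(paths["cds"]), outdir="demo/out", seed=42)
reports = run_characterization(config)
print(reports["table1_like"].head(4).to_string(index=False))
```

```
gene variant species  length  gc_percent mfe  n_uaug  n_uorf uorf_efficiency uorf_context cart_class
G000       a     Syn     255   53.725490           2       2              O2        O1/W1          I
G000       b     Syn     300   56.000000           2       2              O2        O1/W1          I
G001       a     Syn     313   55.910543           2       2              O2        O1/W1          I
G001       b     Syn     325   53.538462           2       2              O2        O1/W1          I
```

Each leader carries the two planted uORFs (both >19 nt from the cap, hence
`O2`; one optimal and one weak context, hence `O1/W1`) and is classified
translation class I — long, uORF-bearing leaders predict low translation.
The 3′ report shows the planted signals with their efficiency calls:

```
gene variant species  length  pas_position pas_hexamer pas_type pas_efficiency
G000       a     Syn     258           138      ATTAAA       NC             LE
G000       a     Syn     258           235      AATAAA        C             VE
```

The canonical hexamer 23 nt from the 3′ end falls inside the 10–45 nt
window and is called very efficient (VE); the distal AUUAAA is low
efficiency (LE).  The same run writes `enrichment.tsv` (ranked k-mers with
observed/expected counts and significance indices) and a `run_log.txt`
recording config, seed and engine choices.  The equivalent shell commands
are `utrlens simulate`, `utrlens run`, and per-stage subcommands
(`utrlens uorf`, `utrlens pas`, `utrlens kmers`, `utrlens mirna`,
`utrlens structure`, `utrlens conserve`).

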