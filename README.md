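# corecrunch

Fast, conservative construction of prokaryotic **core genomes** — the set of
genes present in all or nearly all strains of a species — without computing
all pairwise genome comparisons.

## The problem and the method

Core genomes feed strain phylogenies and population-genetic inference, so
they should contain **true orthologs only**. Conventional tools infer
orthologs from best-bidirectional hits (BBH) over every genome pair, which
scales quadratically with genome count and is easily contaminated by
*hidden paralogs/xenologs*: duplicated or horizontally transferred copies
that masquerade as single-copy genes wherever the real ortholog was lost.

`corecrunch` instead compares every genome against one **pivot genome**:

1. **Families.** Each pivot gene seeds a family; per genome, the best hit
   (identity ≥ *t*, lengths within 20% of each other) becomes the family
   member, and any further hits are recorded as *within-paralogs/xenologs*.
2. **Partially hidden screen.** If a family has within-paralogs, every
   member scoring below the best within-paralog is removed — a genome that
   kept both copies reveals the identity level of the paralogous lineage.
3. **Double outlier screen.** For each putative core family, members
   outside Tukey's fences of the family's identity distribution
   (*distribution 1*, lower fence Q1 − 1.5·IQR, upper Q3 + 1.5·IQR) are
   paralog candidates. A candidate is removed only if it is **also**
   outside the fences of its own genome's identity profile across all
   putative core genes (*distribution 2*). The second test keeps genuinely
   divergent strains in the core: their scores are low everywhere, not just
   in one family.
4. **Core assembly.** Families present in ≥ 90% of genomes (default,
   inclusive) after screening form the core. With `--stringent`, any family
   containing a detected paralog is dropped whole.

A single pivot search is linear in genome count. Because a low-quality
pivot can bias the result, two runs with different pivots can be merged
with `corecrunch consensus`, which keeps consistently inferred families and
rescues core genes missing from one pivot genome.

The package also ships a truth-labelled simulator (`corecrunch simulate`)
that plants the four canonical paralog configurations — none (A),
within-paralogs (B), partially hidden (C), completely hidden (D) — so every
screening behaviour is testable end to end.

## Worked example

```bash
corecrunch simulate --out demo_data --genomes 8 --genes 12 \
    --scenarios A=9,B=1,C=1,D=1 --seed 4
corecrunch run --in demo_data --out demo_run --pivot genome001 --ident 70 --seed 4
```

prints

```
wrote 8 genomes and truth table to demo_data
core genome: 9 families (3 excluded) | pivot genome001 | outputs in demo_run
```

and `demo_run/summary.tsv` begins

```
family_id        n_members  n_within_paralogs  n_partial_hidden_removed  n_double_outlier_removed  status
genome001_g0001  7          0                  0                         0                         below_frequency
genome001_g0002  6          2                  2                         0                         below_frequency
genome001_g0003  8          2                  0                         0                         core
```

Reading the rows: `g0001` lost its ortholog in two genomes by chance and
fell below the 90% frequency threshold (7/8 genomes). `g0002` is the
planted scenario-C family — two genomes carried a co-resident paralog
(`n_within_paralogs = 2`), the partial-hidden screen removed the two
members that were really paralogs in disguise, and the repaired family
(6/8) no longer met the frequency threshold. `g0003` is the scenario-B
family: its two within-paralogs were never members, so the family stays
core with all 8 orthologs. Per-family FASTAs are in `demo_run/families/`,
all parameters in `demo_run/run_log.txt`, and a machine-readable snapshot
in `demo_run/core.json` (which is what `corecrunch consensus` consumes).

Library use mirrors the CLI:

```python
from corecrunch import RunConfig, run
core = run(RunConfig(input_dir="demo_data", out_dir="demo_run2",
                     pivot="genome001", identity_threshold=70.0, seed=4))
print(len(core.families))
```

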