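# Methods

## Signal model

Chemically induced RT stops are read out as read 5′ ends. The library design
ligates an adapter to the tRNA 3′ end and primes reverse transcription from
it, so every cDNA starts at the tRNA 3′ terminus and extends 5′-ward until
the enzyme either reaches the 5′ end or falls off. A blocking adduct —
CMC on Ψ, the ring-opened base after NaBH₄ reduction of D, or the abasic
site left by NaBH₄-driven m⁷G depurination — causes termination one
nucleotide 3′ of the modified base, because the last nucleotide the enzyme
incorporates is the one paired to template position *n + 1*. All calls are
therefore shifted: stops counted at index *n + 1* are attributed to a
modification at index *n*, and stop index 0 (the full-length bin) never
yields a call.

4-thiouridine at position 8 also produces a reproducible stop signal on the
NaBH₄ track and is handled through the catalog like the other borohydride
targets.

## Statistics

Per cluster and stop position, with pooled raw replicate counts:

- γ = Σ reads assigned to the cluster in the treated library / Σ in the
  control, computed per cluster so that expression differences between tRNAs
  do not leak into the test.
- FC = (Stop⁺ + α) / (γ·Stop⁻ + α), α = 1 added symmetrically to absorb
  zero counts. When Stop⁻ = 0 this collapses to Stop⁺ + 1 regardless of γ.
- p = P(X ≥ k) for X ~ Poisson(λ), with k the raw treated stop count and
  λ = γ·Stop⁻ at the same position. λ is floored at 1e−9 to avoid a
  degenerate zero-rate distribution; the pseudocount enters only the fold
  change, not the test, so the two statistics remain interpretable
  separately. A `--literal-tail` debug flag exposes the alternative
  1 − pmf(k) reading for comparison; it is not a tail probability and is
  never used for calling.
- q: Benjamini–Hochberg step-up over all tested positions of a
  treatment/control pair jointly (`statsmodels.stats.multitest`).

Read ends are modeled as Poisson without overdispersion; stop counts at a
position across replicates are sums of independent low-probability events,
and the per-cluster γ removes the dominant between-library scale factor.
The package does not fit a negative-binomial alternative.

A site passes when all four gates hold: q < 0.01, log₂FC > 1, Stop⁺ ≥ 20,
and 100·Stop⁺/coverage⁺ ≥ 2 at the stop position. The FC gate is expressed
on the log₂ scale (log₂FC > 1, i.e. FC > 2); the count and percentage gates
suppress low-coverage positions where a handful of stops would otherwise
produce an inflated ratio. All four thresholds are exposed as options.

Replicates are pooled as raw counts before testing (recorded in the run
metadata); per-library normalized profiles (reads-per-million scaling and
replicate means) are produced for QC only. Pooling was chosen over testing
normalized means because the Poisson test needs integer counts on a single
scale, and γ already performs the between-sample normalization — applying
both would double-correct.

## Treatment pairing and classification

NaBH₄ libraries are tested against the untreated control; CMCT libraries
against the CMCT buffer control. Passing sites are classified by (Sprinzl
label, genomic base) against the catalog:

| treatment | TP entries | valid target bases (type-I side) |
|---|---|---|
| NaBH₄ | D at U 16, 17, 20, 20a, 20b, 21, 47; m⁷G at G46; s⁴U at U8 | U, G |
| CMCT | Ψ at U 13, 31, 32, 38, 39, 40, 55, 60, 65 | U |

G is a valid borohydride target (m⁷G chemistry) but not a carbodiimide one,
so an uncataloged G site is type-I on the NaBH₄ track and type-II on the
CMCT track. CMCT stops at U54 are reported as `ambiguous_m5U`: only
ribothymidine is documented at 54 in bacteria and CMCT is not validated for
it. Stops at position 45 in clusters that also carry a passing m⁷G46 call
are flagged `shadow` rather than counted among the false positives — they
track the neighboring m⁷G, not an independent site. The catalog is a YAML
file; sites validated by an orthogonal method (e.g. MS/MS) can be promoted
to TP entries without code changes.

## Sprinzl coordinate assignment

Labels are assigned structure-guided from the dot-bracket string: the
acceptor stem is the stacked helix at the 5′ end; the D-, anticodon- and
T-arms are the hairpins between its arms, in order. Label ranges follow the
standard numbering (acceptor 1–7/66–72, linker 8–9, D-stem 10–13/22–25,
D-loop 14–21, position 26, anticodon stem 27–31/39–43, anticodon loop 32–38,
variable region 44–48, T-stem 49–53/61–65, T-loop 54–60, discriminator 73,
CCA 74–76). Conventions where real tRNAs vary:

- D-loop insertions: one extra residue is labeled 20a, a second 20b, and
  only a third 17a — matching the relative frequency of these insertions in
  bacterial tRNAs; loops shorter than 8 nt drop 17 first.
- A 3-bp D-stem frees label 13 into the loop.
- Short variable loops drop label 47 first (4-nt loops are 44/45/46/48),
  keeping m⁷G46 anchored; long variable arms insert e1, e2, … between 45
  and 46.
- Anticodon and T loops must be 7 nt; structures that do not segment into a
  cloverleaf raise an error suggesting a user-supplied map, and an override
  map of the right length is accepted verbatim (`--sprinzl-map`).

Internally all indices are 0-based half-open; report tables carry both the
raw index and the Sprinzl label.

## Misincorporation profiling

The untreated track is scanned for positions with coverage ≥ 10 and
mismatch fraction ≥ 0.10 (both configurable). Each record carries per-base
fractions and a one-sided binomial p-value against a 1% sequencing-error
rate, which replaces a genotype-likelihood caller's confidence gate; when
counting from BAM, bases under Phred 20 are excluded from the composition.
Signatures: inosine 34 (ref A, >99% G), m¹A22 (ref A, mismatches dominated
by G/T), m¹G37 (ref G, elevated mismatch). Everything else is emitted
unassigned.

## Simulator

Each read starts at the cluster 3′ end and survives position *i* with
probability 1 − p(i), walking 5′-ward; this sequential-survival model
matches the physical RT process and automatically produces the coverage
drop 5′ of strong stops. p(i) is the background rate (default 0.002)
multiplied by a linear 3′ bias (doubling at the 3′ end by default,
reflecting the enzyme's tendency to terminate early in the 3′ half), or the
planted stop probability (default 0.2) at the position one 3′ of a planted
modification in the matching treatment. The induced stop distribution is
multinomial, so pileups are sampled directly from it; per-cluster depth is
Poisson with mean 2000. Defaults follow the emulated study design: 3
replicates × 4 treatments, 20 clusters, two planted sites per cluster (one
per treatment track) at cataloged positions. Output is byte-identical under
a fixed seed.

Generated tRNAs are cloverleaves with randomized stems and U at the
cataloged target positions (8, D-loop, 13, 32, 38, 39, 54, 55, 60; G at 46)
so that sites are plantable anywhere in the catalog; D-loop lengths 8–10 nt
and variable loops of 4–5 nt give realistic length variation. What the
simulator does **not** model: sequencing errors outside specified miscall
sites, partial 3′ starts or adapter artifacts, RT fall-off from secondary
structure, cluster assignment ambiguity, or modification-specific stop
efficiencies. Passing recovery tests therefore demonstrates that the
statistics and bookkeeping are correct under the stated noise model — not
that real libraries are free of structure-driven false positives, which is
exactly what the three noise gates and the FP classes exist to contain.

## Problem sizes and numerical choices

The test suite and the acceptance script run the default 20-cluster
simulation (≈ 1500 testable positions per treatment pair, ≈ 24 000 reads per
treatment pooled) and 20 null re-simulations; these sizes give stable
recovery estimates while keeping a full run in seconds. Poisson tails use
`scipy.stats.poisson.sf(k−1, λ)`, stable for large k; the brute-force
oracles in the tests sum pmf terms in log space independently of scipy.
Ties in BH are handled by the step-up definition; clusters with zero control
reads are skipped with a warning (γ undefined) rather than imputed.

## Known limitations

- The Poisson background with λ estimated from a single pooled control
  count is slightly anti-conservative at very low coverage; the count and
  percentage gates absorb this in practice (null runs are clean), but
  uncovered corner cases exist when control coverage is near zero.
- Sprinzl assignment expects a four-arm cloverleaf; atypical structures
  (e.g. animal mitochondrial armless tRNAs) need a user-supplied map.
- Type-I/type-II classification is position-based, not tRNA-specific: a
  known-position call in a tRNA never carrying that modification still
  counts as TP_known.
- Identical-sequence clustering cannot separate modification differences
  between identical gene copies; calls are per cluster.
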