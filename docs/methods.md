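# Methods

## Statistical model

### Variance moderation

Per feature and contrast, the pooled two-sample variance $s_g^2$ on
$d_g = n_a + n_b - 2$ residual degrees of freedom is modelled as
$s_g^2 \sim s_0^2\,F(d_g, d_0)$ — equivalently, the true residual
variances follow a scaled inverse-chi-square prior with $d_0$ degrees of
freedom and location $s_0^2$. The prior is fitted by moment matching on
$z = \log s_g^2$, using

* $\operatorname{var}(z) = \psi_1(d_g/2) + \psi_1(d_0/2)$, solved for
  $d_0$ by Newton iteration on the trigamma inverse (tolerance $10^{-8}$);
* $\operatorname{mean}(z) = \log s_0^2 + \psi(d_g/2) - \log(d_g/2)
  - \psi(d_0/2) + \log(d_0/2)$ for $s_0^2$.

If the spread of $z$ does not exceed $\psi_1(d_g/2)$ — what the residual
degrees of freedom alone explain — the fit returns $d_0 = \infty$ (full
shrinkage to $s_0^2$). Features with exactly zero variance are excluded
from the fit with a warning. The moderated statistic uses the posterior
variance $\tilde s^2 = (d_0 s_0^2 + d_g s_g^2)/(d_0 + d_g)$ and a
$t_{d_0 + d_g}$ reference distribution. Numerical conventions:

* $d_0 = 0$ reduces exactly to the ordinary pooled equal-variance $t$ on
  $d_g$ df (verified to $10^{-10}$ against an independent implementation);
* $d_0 = \infty$ uses $t$ with df $= 10^6$ (the normal limit) rather than
  a special-cased normal, for one code path;
* zero posterior variance with zero mean difference yields $t = 0,
  p = 1$ (total on degenerate input), and with a nonzero difference
  $t = \pm\infty, p = 0$;
* the pooled (equal-variance) form is used rather than Welch: the design
  is balanced at $n = 3$ per group and the moderation model is built on a
  single per-feature variance.

### Compound DE call

"Differentially expressed" means all three of: $|\log_2\mathrm{FC}| >
\log_2 2$, raw $p < 0.05$, BH-adjusted $p < 0.20$. The conjunction of the
raw-p and FDR gates is the strictest reading of a joint "p < 0.05 with
20% FDR" criterion; both gates are independently configurable
(`--p-threshold`, `--fdr`), so the alternative reading (FDR targeting
alone) is available by relaxing the other gate.

### Target aggregation and pair calling

A (miRNA, gene) prediction survives when at least `min_sources` (default
3) distinct databases contain it; its score is the geometric mean of the
within-source ranks over the sources where it occurs. Absent sources are
not penalty-padded: the support gate already encodes "enough databases
agree", and geometric-mean-of-present-ranks is the conventional default
of rank-aggregating target tools. "Inversely correlated" is implemented
as strict sign opposition of the two point log2FC estimates: with three
replicates per group, a sample-level correlation estimate is too noisy to
be the operative filter (a Pearson-based rule is available via
`sign_rule="pearson"`). Fold changes of exactly zero never pass, which
keeps the sign law total; such features cannot pass the fold gate anyway.

### Enrichment

Hypergeometric upper tail, inclusive ($P[X \ge k]$), BH-adjusted across
terms, significant at adjusted $p < 0.05$. The background universe is the
union of annotated genes intersected with the assayed mRNA features; a
whole-genome background would overstate enrichment for platform-biased
annotations. No GO-graph propagation or term-redundancy collapsing is
performed.

### Co-expression clustering

Clustering operates on group-mean profiles (6 coordinates), row-z-scored
by default: the biological archetypes of interest are *shapes* across
groups, and unscaled clustering would primarily separate effect
magnitudes (`scale_rows=False` preserves the unscaled reading). K-means
uses 25 k-means++ restarts with a fixed seed; additionally each $k$ is
warm-started from the $k-1$ solution's centroids plus a new center at the
worst-fit point, which makes the best-of SSE curve provably
non-increasing in $k$. The elbow is the $k$ maximizing the discrete
second difference $\mathrm{SSE}(k{-}1) - 2\,\mathrm{SSE}(k) +
\mathrm{SSE}(k{+}1)$; ties resolve to the smallest $k$, a near-linear
curve warns "no clear elbow", and the diagnostic table plus a `--k` flag
keep the choice overridable — elbow reading is ultimately a judgment
call. Core members must have Pearson $r > 0.8$ (strict) to their own
centroid, computed over the six group coordinates; constant profiles have
undefined correlation and are excluded with a warning.

### qPCR and concordance

ΔΔCt: $\Delta Ct_s = Ct_s(\text{gene}) - Ct_s(\text{reference})$, fold
$= 2^{-\Delta\Delta Ct}$, two-sided equal-variance Student *t* on the
ΔCt values (NaN when a group has fewer than two samples — the fold is
still reported). Concordance against an external DE table uses only
fold-change signs and significance flags of the features significant in
the pipeline's own table; magnitudes never enter, so rescaling the
external table is a no-op by construction.

## Synthetic data generator

The generator emulates the statistical skeleton of a six-group
gonadectomy / hormone-replacement design: 700 miRNAs and 5000 mRNAs on
log2 scale, 3 replicates in each of Male C, Female C, ORX, OVX, ORX+T,
OVX+E. Per feature: baseline $\sim N(7, 1.5^2)$ (log2 units), i.i.d.
Gaussian noise with per-feature variance from a scaled
inverse-chi-square$(d_0{=}4, s_0^2{=}0.25^2)$ — so the moderation prior
is well specified and its recovery is itself testable.

Planted structure:

* **Two archetypes.** All planted DE miRNAs (default 30 per archetype)
  carry one of two additive group-effect patterns, scaled by a per-miRNA
  magnitude $\sim U(1.2, 2.5)$: archetype 1 $= (1, 0, 1, 0, 2, 0)$ over
  (Male C, Female C, ORX, OVX, ORX+T, OVX+E) — peak in ORX+T, male groups
  above female; archetype 2 $= (0, 1, 0, 1, -1, 2)$ — trough in ORX+T,
  peak in OVX+E. Integer weights mean every pairwise group delta of a
  planted feature is exactly 0 or ≥ 1.2 in magnitude: the planted truth
  contains no sub-threshold effects, so sensitivity and FDR bookkeeping
  are unambiguous. A consequence mirroring the real system: the
  gonadectomy-only contrasts (ORX vs Male C, OVX vs Female C, ORX vs OVX)
  carry no planted DE — hormone replacement drives the signal.
* **Repression edges.** Each planted miRNA represses 5 dedicated genes,
  each receiving exactly the negated group-effect vector. Exact mirroring
  (rather than a random repression multiplier) keeps every planted target
  above the fold gate, so pair recovery measures the method, not the
  multiplier draw.
* **Target table.** Planted edges appear in 3–5 of 5 sources at top
  ranks. Two kinds of negatives give pair calling a false-positive
  surface: well-supported decoy edges between non-DE miRNAs and non-DE
  genes (~10% of edges), and under-supported edges (1–2 sources) that
  must die at the ≥ 3-source gate.
* **Gene sets.** 40 terms; one term per archetype contains 75%
  (`enriched_term_fraction`) of that archetype's target genes plus random
  padding; the rest are random subsets of 20–200 genes.

What the generator does **not** emulate: probe-level intensities and
array background, batch or spatial artifacts, correlated noise between
features, miRNAs regulating shared targets, partial repression
magnitudes, and annotation incompleteness. Passing recovery tests
therefore demonstrates the pipeline's correctness and power under its own
model assumptions — not its robustness to the messier failure modes of
real arrays, which the preprocessing diagnostics of a real study would
have to address upstream.

## Problem sizes and reproducibility

Recovery metrics are averaged over 20 generator seeds at the default
sizes above; the prior-recovery check uses 10 seeds × 10,000 features.
These sizes give stable estimates (across-seed spread of sensitivity is
~1 percentage point) while keeping the whole suite fast. All randomness
flows from explicit seeds: the pipeline derives a named substream per
stage from the single config seed, so adding or reordering stages does
not perturb the others, and a re-run with the same config and seed
reproduces every output byte-for-byte (`run.log` timestamps excepted).

## Known limitations

* Identifier harmonization (mature vs precursor miRNA names, gene symbol
  aliases) is delegated to a user-supplied alias map; no guessing.
* Expression matrices must be complete; missing values are an error by
  design, not imputed.
* The concordance module consumes external DE tables as published; it
  does not re-analyze external raw data (e.g. sequencing counts).
* Single-factor two-group contrasts only: no covariates, no paired
  designs, no multi-factor linear models.
* The elbow heuristic can be ambiguous on weakly structured data; the
  SSE diagnostic table and the `--k` override exist precisely for that
  case.
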