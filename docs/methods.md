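# Methods

## Fermentation stoichiometry

A fermentation equation is a signed rational map over registered compounds
(negative = consumed). Measured quantities — substrate, acetate, caproate,
butyrate — are *fixed*; H⁺, H₂O, CO₂ and H₂ are *free* and solved from one
linear conservation equation per element plus one for charge. With these
four free species the system is square and nonsingular for any fixed
spectrum over C/H/O species (charge pins H⁺, carbon pins CO₂, oxygen pins
H₂O, hydrogen pins H₂), so the solution is unique. All coefficients are
Python `Fraction`s end to end: a reaction reported balanced has *exactly*
zero residuals, and the acceptance checks on the printed coefficients are
exact equalities, not tolerances. Floats enter only in thermodynamics.

Species are fixed at their pH-7 dominant protonation state (acetate⁻,
lactate⁻, caproate⁻, butyrate⁻ …), and protons are balanced explicitly
through the H⁺ species — the lactate equation genuinely consumes 15 H⁺.

## Transformed Gibbs energies

Δ<sub>r</sub>G′° = Σ νᵢ Δ<sub>f</sub>G′°(i) / |ν(basis)|, at pH 7.0, ionic
strength 0.25 M, 298.15 K. The packaged table
(`src/caproflux/data/compounds.tsv`, versioned and swappable) was built by
applying the Legendre transform with an extended Debye–Hückel ionic-strength
correction,

Δ<sub>f</sub>G′° = Δ<sub>f</sub>G° + N_H·RT ln(10)·pH − RT·α·(z² − N_H)·√I/(1 + 1.6√I),

to standard aqueous formation energies of the listed species (CO₂ and H₂ as
aqueous solutes; caproate from the butyrate value plus two CH₂ increments of
the carboxylate homologous series). Under the transformed convention H⁺
carries Δ<sub>f</sub>G′° = 0. Per-compound uncertainties are
order-of-magnitude standard errors combined as a root-sum-square of
coefficient-weighted terms; this ignores covariances and is documented as an
approximation, so the package's ± values are smaller than
regression-derived ones. The two fermentation equations evaluate to
−256.1 kJ/mol glucose and −24.8 kJ/mol lactate, inside the measured bands.
No pH/ionic-strength transforms beyond this fixed condition are attempted,
and formation energies are tabulated, not estimated.

## The cofactor ledger

Substrate oxidation bookkeeping (per mole):

| substrate | acetyl-CoA | NADH | Fd²⁻ | ATP (SLP) |
|-----------|-----------:|-----:|-----:|----------:|
| glucose   | 2 | 2 | 2 | 2 |
| lactate   | 1 | 2 | 0 | 0 |
| pyruvate  | 1 | 0 | 1 | 0 |

Glucose enters by PTS, so the PEP spent on uptake replaces the hexokinase
ATP and net glycolytic SLP stays 2; pyruvate is oxidized by Pfor (1 Fd²⁻);
lactate oxidation by the confurcating Ldh/EtfAB consumes 1 Fd²⁻ that Pfor
immediately restores, leaving +2 NADH and net zero Fd²⁻. "Reducing-equivalent
pairs" counts NADH + Fd²⁻ two-electron pairs per mole, which makes the
4 : 2 : 1 (glucose : lactate : pyruvate) comparison exact.

Each elongation cycle (condensation → Hbd → Crt → bifurcating Bcd/EtfAB)
consumes 3 NADH and regenerates 1 Fd²⁻; caproate costs two cycles, butyrate
one, so steps = 2·caproate + butyrate. The ledger routes **all** net Fd²⁻
through Rnf (configurable `rnf_protons_per_2e`, default 2, each oxidation
also yielding 1 NADH), vents the remaining NADH surplus as H₂ at 1 : 1, and
converts translocated protons to ATP at `atpase_protons_per_atp` = 4 (the
V-type ATPase ratio taken from *Thermus thermophilus*). Net acetate
production earns 1 SLP-ATP through Ack-Pta; acetate consumption enters
elongation through CoA transferase at zero ATP cost.

Two of these choices were genuinely open and are worth stating:

* **Rnf stoichiometry.** 2 H⁺ per Fd²⁻ is a calibration — the unique
  small-integer choice that, with 4 H⁺/ATP, reproduces both measured yields
  (3.75 ATP/glucose and 0.71 ATP per 2 lactate). It is exposed as
  configuration, and ATP_total is monotone in it (tested).
* **Hydrogenase carrier.** Venting H₂ from the NADH surplus (rather than
  directly from Fd²⁻) is required to close the NADH ledger *and* match the
  H₂ coefficients of both balanced equations simultaneously (1 H₂ per
  glucose; 12 per 21 lactate). Carrier identity is net bookkeeping, so a
  `ferredoxin` donor mode exists but is not the default and yields less ATP.

Feasibility: elongation demand 3s must not exceed oxidation NADH + Rnf NADH
from all Fd²⁻ (including the s the cycles regenerate), i.e. s ≤ (NADH_ox +
Fd_ox)/2. An infeasible request raises with the exact deficit, and the
feasibility check also reports the redox-limited maximal spectrum with the
leftover acetyl-CoA routed to acetate — which is why pyruvate-fed cultures
make acetate instead of caproate even with plenty of electron acceptor.

The ledger is exact: NADH produced = NADH consumed, Fd²⁻ closes to zero, C2
units are conserved, all as `Fraction` identities. Reports render floats.

## Regulator binding-site scanning

The PWM derives from a single consensus, not from aligned sites: allowed
bases at each position share 1 − (4 − k)·ε equally, disallowed bases get
ε = 1e-4, and scores are log₂(p/background) with a uniform background
(configurable GC). N columns are exactly neutral.

The scan threshold is a fraction of the motif's *achievable score range*:
a window passes when (score − min)/(max − min) ≥ threshold (default 0.7).
This min–max relative score is the convention of common PWM scanners and
was chosen deliberately over a fraction of the maximum score: with a sharp
ε the maximum-fraction rule rejects even single-mismatch sites, while the
relative score degrades smoothly (≈0.93 at one mismatch of the 18-mer Rex
operator) and keeps random background negligible (a window needs ≤4
mismatches at 14 informative positions to pass 0.7). A 1e-9 slack below
the cutoff keeps windows that tie the threshold included regardless of
float summation order, which is what makes scanning exactly
strand-symmetric. Absolute scores of published site tables are *not*
reproduced — the scoring/threshold internals behind them are unstated — but
their mismatch ordering is, and is tested.

Both operator consensi are palindromes, so minus-strand scanning would
duplicate every site; palindromic motifs are scanned on the plus strand
only. Offsets are reported relative to the downstream gene's translation
start, negative upstream, on the hit's strand (for a minus-strand gene the
5′ region lies to its right). Intergenic regions are the maximal CDS-free
intervals, each annotated with its downstream gene per strand, so a
divergently transcribed pair shares one upstream interval.

## Expression summaries

TPM is the length-normalized rate scaled to 1e6; differential calls use
strict inequalities (|log₂FC| > 1, padj < 0.05) because boundary handling
changes counts; enrichment is the upper-tail hypergeometric P(X ≥ k) with
no multiple-testing correction, flagged at 0.05/0.01, reported only for
categories with more than `min_genes` (default 5) members of the tested
universe (the full gene table, not the differential subset). The pipeline
consumes precomputed log₂FC/padj columns — differential model fitting is
upstream of its scope. 2^−ΔΔCT is algebraically pinned to 1.0 for the
control sample; concordance is a plain Pearson r on log₂ fold changes.

## Synthetic data

The generators define the test conditions; their defaults are fixed and not
tuned per run:

* **Genomes** — CDS (300–900 nt) alternating with intergenic gaps
  (80–300 nt, floored at motif length + 4), uniform base composition,
  planted consensus instances on random strands with at most
  ⌈mutation_rate·L⌉ substitutions (default rate 0.05 → ≤1 for the 18-mer).
  Intergenic background is rejection-sampled until the scanner finds no hit
  outside a planted site at the generator's threshold, so truth files are
  the complete hit set and precision is 1.0 by construction. CDS content is
  random sequence: no operon structure, codon usage or promoter realism is
  attempted, so recovery tests validate the scanner's arithmetic, not its
  behaviour on real genomes.
* **Expression** — log-normal baseline means (median ≈100 counts, log-sd
  1.2), negative-binomial counts (dispersion 0.05, 3 replicates per
  condition, sizes chosen to mirror a ~2k-gene bacterial transcriptome),
  planted log₂ effects ±Uniform(1.5, 5) on `n_de` genes. The emitted table's
  log₂FC is the realized estimate (summed counts, 0.5 pseudocount) and padj
  comes from a two-sided conditional binomial rate test with
  Benjamini–Hochberg — a deliberate stand-in for a negative-binomial GLM,
  adequate at low dispersion, not a reimplementation of one. Planted-truth
  recovery (sensitivity ≥0.9) therefore certifies the filter, not any
  differential model.
* **Fermentation measurements** — truth spectrum + Gaussian noise with sd =
  5% of each species (default), truncated at zero. Note that the solved H₂
  coefficient is a steep linear function of the measured coefficients
  (6·lactate + 4·acetate − 16·caproate − 10·butyrate for the lactate
  equation), so it amplifies measurement noise roughly 40-fold relative to
  the substrate; the estimate is unbiased (tested over 200 seeds) but
  precise recovery needs sub-percent measurement error.

All generators run off a single `numpy` PCG64 generator seeded from the
spec, so identical spec + seed gives byte-identical outputs.

## Numerical and interface choices

Internal coordinates are 0-based half-open everywhere; GFF3 conversion
happens only at the format boundary. Ledger and balancer arithmetic is
exact; thermodynamics and PWM scores are floats with documented slacks.
Site reports sort by score descending with leftmost-coordinate
tie-breaking. CLI subcommands exit nonzero on any domain error and never
write partial reports.

## Problem sizes

The planted-site recovery analysis uses ten genomes of 100 planted sites
each (≈80 kb apiece); differential recovery uses 100 seeds of 500-gene
datasets (and 20 null seeds); the enrichment oracle sweeps every
hypergeometric parameterization with a universe of ≤25 genes. These sizes
make every property estimate stable at a few-percent resolution while the
whole suite stays interactive.

## Known limitations

Gibbs energies are tabulated at one condition; no metabolite speciation,
kinetics, growth yield, or flux balance with an objective; no motif
discovery or operon prediction; enrichment universes with unannotated genes
count them in N but in no category; the qPCR generator adds Gaussian noise
on the log scale rather than simulating amplification curves.
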