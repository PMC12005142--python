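# Methods

## Scope and data model

`pbscan` operates on per-site, per-individual read observations (base,
Phred quality, strand) or on precomputed genotype likelihoods in Beagle GL /
VCF-GL form. Sites are biallelic with a declared major/minor allele; all
likelihood triples count copies of the **minor** allele and are stored
max-rescaled (Beagle convention), with the uninformative triple (1, 1, 1)
marking missing individuals. Everything upstream of the pileup — alignment,
duplicate marking, base-quality recalibration — is out of scope, as are
read-level bias filters (base-quality, mapping-quality and end-distance
tests) that require alignment metadata this data model does not carry.

## Genotype likelihoods and MAF

The GL model is the independent-error allele-sampling mixture: a read's base
`b` given genotype `g` minor copies has probability
`(1−g/2)·e(b|major) + (g/2)·e(b|minor)` with `e(b|a) = 1−ε` on a match and
`ε/3` otherwise, ε decoded from the read's quality. Reads below the
base-quality cutoff (default Q20) or carrying a third allele are discarded.
The computation is done in log space and is exact; a brute-force oracle that
instead enumerates the chromosome-of-origin of every read (2^R terms)
verifies it to 1e-12 in the tests.

Per-site minor-allele frequency is the EM maximizer of
`Π_i Σ_g GL_ig · Binom(g; 2, f)`; initialization f₀ = 0.1, stop at
|Δf| < 1e-6 or 100 iterations. Sites where every individual is
uninformative get a NaN sentinel and are excluded downstream. The
MAF > 0.05 screen (strict inequality) is applied before structure
inference, mirroring standard practice for admixture estimation.

## Site filters

Three independent predicates, defaults `k=10` individuals with `u=1` read,
heterozygote-excess α = 1e-6, strand-bias α = 1e-4:

- **Coverage**: at least k individuals with depth ≥ u (inclusive).
- **Heterozygote excess**: one-sided exact test on the Levene/Haldane
  conditional distribution of the heterozygote count given sample size and
  minor-allele count, `p = P(het ≥ observed)`. One-sided because only a
  *surplus* of heterozygotes marks collapsed paralogs; a deficit is common
  biology (inbreeding, substructure). Genotype counts come from GL hard
  calls at posterior ≥ 0.95 under the site's MAF–HWE prior, uncalled
  individuals excluded — this keeps the filter usable at 2× without an
  external genotype caller, a deliberate departure from callers that filter
  on their own hard calls.
- **Strand bias**: two-sided Fisher exact test (minimum-likelihood rule, the
  conventional 2×2 definition) on the major/minor × forward/reverse table;
  degenerate margins return p = 1.

Both exact tests are validated against exact-integer enumeration oracles to
1e-10, and a null simulation confirms the combined rejection rate at these
thresholds is negligible on clean data.

## SAF and SFS estimation

The sample-allele-frequency likelihood is built by the dynamic program
`q_i(j) = Σ_g q_{i−1}(j−g)·GL_i(g)·C(2,g)`, finished with
`L(j) = q_N(j)/C(2N, j)` — i.e. genotype configurations are weighted by
within-individual arrangements and normalized by the arrangements of j
copies among 2N chromosomes. Each step is max-rescaled to avoid underflow;
relative likelihoods are exact (enumeration oracle at N ≤ 4, 1e-10). The
spectrum is folded by construction (minor-allele counts): no ancestral
states are assumed anywhere.

The 1D/2D SFS η is fit by EM from a uniform start: site posterior
`P_s(j,k) ∝ η(j,k)·L₁ₛ(j)·L₂ₛ(k)`, M-step η′ = mean posterior; stop at
max|Δη| < tol (default 1e-8) or max_iter (default 500). Sites with an
identically zero SAF product are excluded with a warning. Sites are treated
as independent — linkage is ignored, as in the SNP-wise estimators this
implements. With one-hot SAFs the EM collapses to the empirical joint
histogram after one step, which the tests assert exactly.

## FST, PBS and peak calling

Per-site components use the Hudson/Bhatia moment estimator
(`N`, `D` above) evaluated as posterior expectations over (j, k) under the
2D-SFS prior. The underlying study's tooling cites the Reynolds (1983)
estimator; both are ratio-of-sums moment estimators and the Hudson form has
the cleaner small-sample behaviour and the closed drift relation
`E[N]/E[D] = (c₁+c₂)/2` under Balding–Nichols used throughout the tests.
This is a recorded design choice, not a claim of numerical equivalence.

Window FST is Σa/Σd over the window's sites — the ratio of sums, never the
mean of per-site ratios. Windows are 1-based half-open [start, start+W),
starting at 1, 1+step, …; defaults W = 50 kb, step = 10 kb, with a 1 kb /
500 bp zoom configuration for candidate regions. Windows with fewer than
`min_sites` (default 10; a robustness default, not an estimate-changing
parameter) are reported missing and never enter percentile ranking.

PBS_i = (T_ij + T_ik − T_jk)/2 with T = −log(1−FST); negative window FST is
clamped to 0 before the log (unclamped values stay in the window table for
audit), FST = 1 maps to +inf and flags the window. Peaks: the empirical
(1 − top_fraction) quantile of non-missing window PBS (default top 0.1%,
strict >, ties excluded) defines top windows; the highest seeds a cluster
absorbing top windows within 1 Mb center-to-center; clusters with ≥ 6 top
windows are reported, position = best window's start. The ≥ 6 convention is
used (rather than > 6) so a 6-window cluster is a peak.

## Admixture and PCA

Admixture: likelihood `Π_i Π_s Σ_g GL_isg·Binom(g; 2, h_is)`, `h = QF`,
fit by EM in which each allele copy carries a latent ancestry component and
the unknown genotype is marginalized through the GLs — multiplicative
updates of the NGSadmix/ADMIXTURE family rather than a Newton-type
optimizer; what is preserved from the study protocol is the likelihood model
and the multi-restart regime (default 3 restarts × up to 1000 iterations,
best final likelihood reported). Component frequencies are clamped to
[1e-6, 1−1e-6] to avoid absorbing states; Q rows are renormalized each
step. Label switching is resolved explicitly (`align_labels`, assignment
maximizing Q·Q_ref overlap) before any reporting.

PCA: expected genotype dosages under per-individual frequency priors,
standardized by √(2f(1−f)), covariance C = XXᵀ/S; the top `n_pcs`
eigenvectors (default K−1 = 2, with K = 3 matching the three-ancestry
framing) reconstruct individual frequencies and the procedure iterates
`n_iter_indf` times (default 2). Individual frequencies are clipped to
[1e-4, 1−1e-4]. Monomorphic or missing-MAF sites must be filtered first and
raise an error otherwise.

## The synthetic-data generator

The generator emulates the study design this pipeline targets: a focal
cohort of 33 diploids at ~2× coverage plus two related reference panels
(default 25 each), biallelic SNPs with independent sites, genome-wide
pairwise FST in the 0.01–0.05 range, optional admixture, and a localized
region of exaggerated focal divergence. Concretely: ancestral frequencies
uniform on [maf_floor, 1−maf_floor] (default floor 0.05, an ascertainment
stand-in), folded so the tracked allele is the ancestral minor;
Balding–Nichols drift `p_i ~ Beta(p(1−c)/c, (1−p)(1−c)/c)` per population —
so `E[(p_i−p)²] = c·p(1−p)` and pairwise Hudson FST ≈ (c_i+c_j)/2. Default
drifts (0.068, 0.020, 0.012) put the three pairwise FSTs at 0.044 / 0.040 /
0.016, the genome-wide scale of the focal trio. Mean depth 2.0 (the study
cohort averaged 1.945×), error rate 0.01 (Q20), Poisson depth, uniform
miscalls to the three other bases, Bernoulli(½) strands, a single fixed
Phred quality per run (uniform quality keeps the GL oracles exact). Sweeps
displace the focal minor-allele frequency by `p′ = p + δ(1−p)` inside the
interval; admixed genotypes are Binomial(2, Σ_k Q_ik F_ks).

What the generator does **not** model: linkage disequilibrium and haplotype
structure, recombination, indels, machine-specific quality profiles,
duplicates and mis-mapping. Passing tests therefore demonstrate correctness
of the estimators under their own assumptions (independent sites, known
alleles, uniform error) — not robustness to real-data artifacts such as LD
between windows, reference bias, or quality miscalibration.

## Desk-scale test conditions

The validation suite runs on one CPU in minutes, so its simulations are
scaled down from genome scale; the scaling choices are part of the package's
test design:

- FST recovery: 50,000 sites, 15+15 individuals, 2×, ε = 0.01, five seeds;
  the genome-wide ratio-of-sums estimate must fall in [0.035, 0.065] around
  the true 0.05.
- Sweep power/null calibration: 10 Mb genome, 10,000 SNPs, three
  populations of 15, δ = 0.8 sweep over 100 kb. At this scale a 0.1% tail
  of ~1000 windows cannot contain 6 windows by construction, so the scan
  runs at 20 kb / 10 kb resolution with a 1% tail — ~10 top windows, the
  same order as a 0.1% tail of a genome-scale window count — keeping the
  overlapping-window design and the ≥ 6-window / 1 Mb merge rule intact.
  The 5× overlap of the full-scale 50 kb / 10 kb configuration makes null
  extremes arrive in contiguous runs at this few-window scale, which is an
  artifact of desk scale, not of the method; production defaults remain
  50 kb / 10 kb / 0.1%.
- SFS EMs inside the scan tests run at tol 1e-5–1e-6 and 80–150 iterations:
  window-level FST ratios stabilize long before the spectrum's tail entries
  do.

## Numerical notes and limitations

- All randomness flows from `numpy.random.SeedSequence`; the pipeline
  derives per-stage child seeds from one master seed, so stages are
  independently reproducible and reruns are byte-identical.
- EM monotonicity (MAF, SFS, admixture) is asserted in tests at every
  iteration; the admixture clamp can in principle break monotonicity at the
  boundary but at 1e-6 never does measurably.
- The SAF convention (C(2,g) within-individual weights, C(2N,j)
  normalization) is validated against its own enumeration oracle;
  alternative published weightings exist, and no claim of equivalence to any
  specific tool's convention is made.
- Ties at the PBS quantile threshold are excluded (strict >); with
  continuous statistics ties have measure zero.
- Genome-wide FST on sweep-containing simulations includes the sweep sites'
  contribution to the ratio of sums, so a strong implanted sweep visibly
  raises the focal pairs' genome-wide FST at desk scale (hundreds of sweep
  sites among thousands); on null simulations the GL-aware estimate agrees
  with the true-genotype estimate to the third decimal.
- The site list is an input: no SNP discovery or major/minor inference from
  data is performed, and real-data input must declare major/minor alleles.
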