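# Methods

`thermosize` analyses how experimental warming changes the mean cell size
and nucleic-acid content (NAC) of marine heterotrophic bacterioplankton, as
seen by flow cytometry, and ships a synthetic-experiment generator that
plays the role of the (undeposited) raw data. This note records the models,
the parameter choices, and the places where a design decision was genuinely
open.

## The experimental design being emulated

Each monthly experiment splits seawater into a whole-community treatment
(C, 200 µm pre-filtered) and a grazer/phytoplankton-free treatment (F,
0.8 µm pre-filtered), incubated in triplicate at ambient − 3 °C, ambient,
and ambient + 3 °C — 18 bottles per month — and sampled roughly twice a day
for about six days. Every sampling yields a cytometry acquisition with
side scatter (SSC, a cell-size proxy) and green fluorescence after
nucleic-acid staining (an NAC proxy) per event, with 1 µm reference beads
as an internal standard. The canonical HNA (high-NAC) and LNA (low-NAC)
bacterial populations are separated on green fluorescence.

## Synthetic-data generator

**Event clouds.** Each acquisition is a mixture of three clusters — LNA,
HNA, beads — log-normal in both channels. Cluster locations are arithmetic
means, so bead normalization maps the bead mean to exactly 1 relative unit
in expectation, and the mean of the per-event spherical volumes equals the
injected mean volume exactly (the log-normal Jensen correction is applied
analytically). Log-normality was chosen for positive support and the right
skew typical of cytometric signals.

**Injected temperature effects.** The per-°C effects on mean volume and
NAC are linear: `ambient + slope × (T − T_ambient)`. Default annual-mean
slopes are, per group × treatment (size, in 10⁻³ µm³ °C⁻¹): HNA F −4.2,
LNA F −1.6, HNA C −5.3, LNA C −0.5; NAC (10⁻³ fru °C⁻¹): −2.2, −1.2, −4.4,
−0.4. True monthly slopes scatter around these means with SD equal to the
corresponding annual-mean standard errors (a deliberately conservative
month-to-month spread), with a correlation of 0.75 between each
population's size and NAC deviations so that slope–slope correlations are
recoverable downstream. Rare draws that would push the HNA NAC location
below 1.3 × the LNA location are clamped: the two groups are *defined* by
their fluorescence separation, and a cytogram in which they merge is not a
valid realization of the design.

**Size–NAC correlation.** The headline event-level correlation between
volume and NAC (target 0.82) is a *pooled* quantity over LNA + HNA events.
Pooled moments of a log-normal mixture are available in closed form, so the
generator solves (Brent root finding) for the within-cluster Gaussian
log-scale correlation that makes the pooled linear Pearson equal the
target. Whether the target is attainable depends on the cluster geometry;
the default dispersions (log-SD 0.08 in both channels) were chosen so that
it is, while keeping the HNA/LNA fluorescence modes ≈ 4.7 combined SDs
apart (cleanly gateable, as in real bivariate cytograms).

**Growth.** Per-bottle abundance follows lag → exponential → saturation:
flat at N₀ until the lag ends (default 1 d), then exponential at the
Boltzmann–Arrhenius rate μ(T) = μ_ref · exp(−E/k · (1/T − 1/T_ref)) with
k = 8.617 × 10⁻⁵ eV K⁻¹, then capped at the carrying capacity K (default
N₀ = 3 × 10⁵, K = 2 × 10⁶ cells mL⁻¹ per group). The cap is the sharp
limit of a logistic; it keeps ln N exactly linear across the whole
exponential phase with slope μ(T), which is the property the growth-rate
estimator is specified against. Default activation energies: 0.65 eV for
HNA (0.30–0.35 eV for LNA), with μ_ref 0.4–0.9 d⁻¹ by group and treatment.

**Noise model.** One master seed is split deterministically (numpy
`SeedSequence.spawn`) into per-bottle and per-acquisition substreams:
identical (design, truth, seed) triples are byte-reproducible while
replicates stay independent. Noise terms, all configurable and all zeroed
by `TruthParams.zero_noise()`: bottle-level offsets on mean volume/NAC
(SD 5% of ambient), per-time-point jitter (3%), multiplicative abundance
noise (CV 5%), per-acquisition instrument gain (log-SD 0.10, cancelled by
bead normalization), bead CV 5%, and Poisson event counts. Mean size also
drifts by growth phase (+2% in lag, −3% in exponential) so that
whole-experiment vs growth-phase mean comparisons are exercisable.

**Acquisition size.** Event counts per acquisition are not reported for
the real instrument runs; the generator targets 3 000 bacterial events
plus 300 beads per acquisition (a typical bacterioplankton counting
acquisition), with the acquired volume back-computed from the current true
abundance, emulating variable run time at fixed counting effort.

**Community tables.** One community is drawn per month × treatment.
CARD-FISH: four probe proportions (SAR11 0.300, Rhodobacteraceae 0.120,
Gammaproteobacteria 0.150, Bacteroidetes 0.134; sum 0.704 of DAPI) vary
log-normally across months (SD 0.35) and only slightly across samples
(SD 0.05); counts are multinomial with 800 DAPI cells per sample, two
replicate bottles counted per treatment cell. ARISA: 35 true fragments per
community, 8 of them dominant (structured Dirichlet), uniform lengths in
120–950 bp; per-sample intensities jitter log-normally (SD 0.15) and
lengths by a 0.4 bp measurement error, making 3-bp binning non-trivial;
raw intensities are unnormalized and a couple of out-of-range peaks per
sample exercise the filters. Named samples can be planted as outliers with
independent communities.

## Cytometry

Gating is automatic and auditable rather than manual: beads are removed
first (events within 0.4 natural-log units of the nominal bead position in
both channels), then a threshold on log green fluorescence is placed at
the minimum of a smoothed histogram density (Silverman bandwidth, 512-bin
grid) between the two most prominent modes; a two-component Gaussian
mixture is the fallback for shoulder-shaped densities, and a unimodal
distribution yields a flagged, unsplit result with all bacteria labelled
`unassigned`. Normalization divides both channels by the arithmetic bead
means (≥ 20 beads required), making all downstream quantities invariant to
instrument gain.

SSC → diameter uses a configurable strictly monotone calibration
(power law by default, `d = ssc_ru^0.5` µm, which maps the 1 µm beads to
1 µm and puts ambient volumes in the observed 0.035–0.091 µm³ range);
volume assumes spheres, V = (π/6)d³. Volume is converted **per event and
then averaged** — the mean cell volume is the biological quantity — rather
than converting the mean scatter; the difference is a Jensen gap of a few
percent at the default dispersions. Natural logarithms are used
throughout. Dye inter-calibration (Syto 13 → Sybr-Green I) is an OLS line
fitted on paired samples.

## Temperature responses

Per-bottle summaries are unweighted means over all time points (≥ 2
required); growth-phase-only means and at-maximum-abundance values are
also computed for robustness comparisons. The temperature response is the
OLS slope of the nine per-bottle means against incubation temperature,
with the closed-form standard error, a 95% t confidence interval
(df = n − 2), and significance = CI excludes zero. Regressions proceed
with as few as 4 bottles when replicates are missing, recorded in the
output.

Percent change per °C is −100 × slope / ambient value, positive meaning
reduction; "ambient value" defaults to the mean of the three
ambient-temperature replicates at t = 0 for that month/treatment/group
(normalization to the overall initial value is also implemented). NAC
percent loss converts to base pairs by equating each group's ambient NAC
to a genome anchor — 2 Mbp (LNA) and 5 Mbp (HNA) — so
kbp °C⁻¹ = percent/100 × anchor × 1000.

Growth rates are OLS slopes of ln N vs time over the linear phase, found
by exhaustive search over contiguous windows of ≥ 3 points: among windows
with r² ≥ 0.95 the largest slope wins, near-ties (10⁻⁹ relative) resolved
by longer window then earlier start; if no window qualifies the best-slope
window is returned flagged, and non-positive winners are flagged (the LNA
whole-community case). Activation energy regresses ln μ on 1/(kT) over all
bottles with positive rates and reports E as the negated slope, so E > 0
means faster growth when warmer; the raw slope is kept alongside.

**Known estimator bias.** The max-slope window rule is slightly
anticonservative under noise: with many candidate windows (long
exponential phases, i.e. low temperatures) the selected slope is inflated
by a few percent, which compresses Arrhenius slopes and attenuates
recovered activation energies by roughly 10–15% at the default 5%
abundance noise. The rule is kept because it is simple, deterministic and
auditable; the attenuation disappears as noise → 0 (recovery is then exact
to 10⁻¹⁰ eV).

**Unit-scale caveat.** Slopes of ~10⁻³ µm³ °C⁻¹ on ambient volumes of
~0.05 µm³ imply percent reductions of several % °C⁻¹, far above the
0.45% °C⁻¹ headline scale; the scale of the per-bottle means entering the
published regressions is ambiguous. The package treats units consistently
end to end (so its percent outputs follow from its slope inputs) and keeps
the percent and absolute-slope pipelines separate; the base-pair
conversion examples are exercised on percent-scale inputs directly.

## Community structure

CARD-FISH percentages are 100 × count/DAPI per probe with summed coverage
reported. ARISA filtering order is: length window 100–1000 bp (inclusive)
→ normalize intensities to sum 1 → drop peaks below 0.09 (inclusive ≥
retained) → renormalize; the cutoff applies to normalized intensities
since raw fluorescence scales are arbitrary. Binning enumerates frames
anchored at 100.0 + k·0.1 bp (k = 0…29) with 3-bp bins `[start,
start + 3)`, scores each frame by the mean pairwise Bray–Curtis
*similarity* of the resulting table, and keeps the best frame (ties → the
smallest offset) — the published shifting-window criterion. Bray–Curtis is
Σ|x−y|/Σ(x+y); all-zero sample pairs are undefined and flagged. Trees are
UPGMA by default (complete/single available), serialized as Newick with
ultrametric branch lengths (leaf depth = merge height / 2), with
cophenetic distances exposed. Clustering-by-month is quantified as the
fraction of month groups whose samples form an exclusive clade; singleton
groups are counted separately.

## Problem sizes used by tests and the acceptance script

Calibration claims are checked at the scales they are stated for: 10⁵
events for gating accuracy and the pooled correlation, 500 replicate
month-experiments (moment-level simulation) for CI coverage and slope
unbiasedness, 500 replicates for Arrhenius noise recovery, 100 random
instances for the OLS and binning brute-force equivalences, and the full
12-month × 18-bottle event-level design for the end-to-end determinism
check and the acceptance script's Table-1-style recoveries.

## Limitations

The generator emulates the incubation design, not the ocean: it contains
no seasonal climatology of ambient sizes, no grazer or viral dynamics (the
C/F contrast is only a difference in truth parameters), no doublets,
spillover or autotroph channels, and its clusters are exactly log-normal.
Passing tests therefore demonstrate that the estimators recover known
truths under the stated noise model, not that the biological conclusions
hold for any particular sea. Event tables are plain delimited text;
binary cytometry file formats are out of scope.
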