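# Methods

`fieldqsar` implements ligand-based 3D-QSAR for a congeneric small-molecule
series: rigid scaffold alignment, molecular interaction fields sampled on a
shared lattice (CoMFA potentials and CoMSIA similarity indices), partial
least squares regression with leave-one-out validation, a combinatorial
search over field subsets, and coefficient×standard-deviation contour maps.
This note records the model, the parameters that matter, the numerical
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Model

**Alignment.** Every molecule is rigidly superposed onto a template through
a user-designated common-scaffold atom correspondence (explicit map or
SMARTS substructure match), using the Kabsch least-squares rotation with
reflection correction. Alignment is rigid-body only: input conformers are
assumed pre-minimized, and flexible fitting is a different algorithm class.
Internal distances are preserved to 1e−9 Å and the operation is idempotent.

**Lattice.** An axis-aligned grid covers the union bounding box of the
aligned set expanded by a margin on every side, with the origin at the box
minimum and `dims = floor(extent/spacing) + 1` per axis. The flattened
point order runs z-fastest, matching the OpenDX convention.

**CoMFA fields.** At each grid point q a probe atom (sp³ carbon, vdW radius
1.52 Å, charge +1 e) accumulates

- steric: `E_S(q) = Σ_i 4 ε_ip [(σ_ip/r_iq)^12 − (σ_ip/r_iq)^6]`, with
  Lorentz–Berthelot combination of per-element (ε, σ); σ per element is
  derived from the Bondi radius so the pair minimum sits at the sum of
  radii. Truncated at +30 kcal/mol (attractive wells are kept).
- electrostatic: `E_E(q) = 332.17 · w_i · q_probe / (ε(r)·r_iq)` with the
  distance-dependent dielectric `ε(r) = r`, i.e. a 1/r² law, clamped to
  ±30 kcal/mol. Grid points whose steric energy sits at the truncation
  value are flagged; their electrostatic entries are replaced by the
  training-set column mean at matrix assembly (recorded, never silent),
  because Coulomb values inside the repulsive core are meaningless and
  would otherwise dominate the regression.

**CoMSIA fields.** Five Gaussian-attenuated similarity indices,

    A_k(q) = − Σ_i  w_probe,k · w_ik · exp(−α r_iq²),   α = 0.3,

for k ∈ {steric, electrostatic, hydrophobic, H-bond donor, H-bond
acceptor}, probe radius 1.00 Å, charge +1, donor/acceptor +1. Atom weights
w_ik: steric = r_vdW³ (Bondi radii); electrostatic = the PEOE partial
charge; hydrophobic from a rule-based atomic table (apolar carbons and
halogens positive, N/O and their hydrogens negative — the table ships with
the package, is fully configurable, and its hash is recorded in every
report, since the original implementation's table is proprietary);
donor/acceptor ∈ {0, 1} placed on the heavy atoms themselves (no projected
lone-pair pseudo-sites; the projection geometry is not specified anywhere
we could follow). The Gaussian needs no cutoff.

**Partial charges.** PEOE (partial equalization of orbital
electronegativities): χ(q) = a + b·q + c·q² per (element, hybridization)
with the 1980 coefficient table; each iteration k moves
`(χ_hi − χ_lo)/χ⁺_lo · 0.5^k` across every bond (χ⁺ is the cation
electronegativity of the less electronegative partner, 20.02 eV for H);
6 iterations by default. Total charge is conserved exactly and
symmetry-equivalent atoms receive equal charges. Only the σ part is
implemented; users needing a π correction can supply externally computed
charges through MOL2 input, which the reader preserves verbatim.

**Descriptor matrix.** Field blocks are concatenated column-wise. Columns
whose training-row standard deviation falls below a per-family threshold
(2.0 kcal/mol for CoMFA, mirroring the usual minimum-σ filter; 0 for
CoMSIA — constant columns are always removed) are dropped with a recorded
reason. `block_standard` scaling divides each block by the square root of
its total column variance so every field enters the regression with equal
total variance weight; `none` leaves values untouched.

**PLS.** Single-response NIPALS on column-centered data, deflating X after
each component; coefficients are back-transformed to the original column
scale. At full rank the fit coincides with least squares (tested at 1e−8
against the normal-equations solution and against scikit-learn's NIPALS).

**Validation.**

    Q² = 1 − Σ(Y_pred − Y_exp)² / Σ(Y_exp − Y_mean)²

over leave-one-out predictions of the training rows, with Y_mean the
full-training-set mean. Each fold refits centering and scaling on its n−1
rows; the kept-column set is frozen from the full training matrix so Q²
remains comparable across field subsets (whether the original software
refiltered per fold is unknowable; the choice is flagged in reports).
Companion statistics: `SEP = sqrt(PRESS/(n−c−1))`, `R²_ncv = 1 − RSS/SS`,
`SEE = sqrt(RSS/(n−c−1))`, `F = (R²/(1−R²))·((n−c−1)/c)` (the conventional
QSAR F-ratio, consistent with SEE's denominator), and
`R²_pred = 1 − PRESS_test/Σ(y_test − ȳ_train)²` on the held-out set.
Per-field contributions are `Σ_j |b_j|·sd_j` over the field's kept columns,
normalized across all kept columns; they are non-negative and sum to 1.

**Component count (OPN).** Default: maximize LOO Q², ties within 1e−6
resolved toward the smaller count. An alternative `min_see` criterion
(smallest fitted standard error) is selectable; the full per-component
table of Q²/SEP/SEE is always emitted so the choice is auditable.

**Field-combination search.** All 31 non-empty subsets of the five CoMSIA
fields are assembled, tuned and scored independently; ranking is Q²
descending, ties toward smaller OPN, then lexicographic subset label. No
multiplicity correction is applied to the 31 parallel models.

**Contour maps.** For each kept column of a field, value = PLS coefficient
× training-column standard deviation, placed on the lattice (dropped
columns are zero and excluded from thresholding). Favored/disfavored
regions default to the 0.80/0.20 quantiles of the kept signed values
(linear-interpolation quantiles, per field); a `cumulative` mode instead
takes the smallest sets of extreme points carrying the top/bottom shares of
Σ|value|. Quantiles were chosen as the default because they are
unambiguous and reproducible; contribution-level thresholds in legacy
software are not precisely documented. Maps export to OpenDX scalar grids
(via GridDataFormats) with a JSON sidecar carrying thresholds and masks.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid spacing | 2.00 | Å | standard CoMFA/CoMSIA lattice resolution |
| lattice margin | 4.0 | Å | "beyond the molecules" is conventionally ~4 Å; configurable |
| CoMFA probe | C sp³, r 1.52, q +1 | Å, e | standard probe atom |
| energy truncation | 30 | kcal/mol | standard steric/electrostatic cap |
| dielectric | ε(r) = r | — | the standard reading of "distance-dependent dielectric" |
| CoMSIA probe | r 1.00, q +1, D/A +1 | Å, e | standard similarity-index probe |
| attenuation α | 0.3 | Å⁻² | standard Gaussian attenuation factor |
| min-σ filter | 2.0 CoMFA / 0 CoMSIA | kcal/mol / — | usual column filtering defaults |
| PEOE | 6 iterations, damping 0.5^k | — | standard convergence schedule |
| vdW radii | Bondi | Å | documented, configurable |
| contour levels | 0.80 / 0.20 | quantile | standard favored/disfavored levels |
| split ratio | 2:1 train:test | — | standard external-validation split |
| max components | 10 | — | comfortably above typical OPN values (6–7) |

## Synthetic benchmark

Real structure files for a published antagonist series are rarely packaged
in machine-readable form, so the generator builds a series with the same
statistical shape: ~60 congeneric molecules (n configurable) sharing a
rigid fused-bicyclic 12-atom scaffold — identical coordinates across
molecules, hence pre-aligned by construction — with two substituent sites.
Mirroring how congeneric series are actually assembled, each site draws its
R-group from a finite palette (8 groups per site, sampled once per seed:
1–4 atoms with randomized positions, partial charges, hydrophobicities and
donor/acceptor flags), plus 0.05 Å per-molecule coordinate jitter. The
palette gives the field matrix the low-rank latent structure real SAR data
has; fully i.i.d. atom clouds would instead produce a noise-like,
full-rank field block whose planted functional is ill-conditioned.

Activities are a known sparse linear functional of the molecule's own
hydrophobic similarity field: 8 planted grid points, chosen as the
highest-variance columns kept at least 2 grid cells apart (adjacent columns
are nearly collinear, and a functional with difference-of-neighbor terms
would test numerical conditioning rather than signal recovery), with
coefficients of random sign and magnitude 0.5–1.5, plus Gaussian noise at
10% of the signal standard deviation by default. The generator returns the
ground truth (lattice, planted coefficients, noise-free signal) for
recovery tests, and everything is bit-reproducible from one seed
(default 20140915).

On this benchmark the 31-subset search selects a hydrophobic-dominated
model with LOO Q² ≈ 0.98 at 10% noise and ≥ 0.999 in the noise-free
variant, and the planted field carries the largest contribution fraction.
An affine rescaling utility maps generated activities exactly onto a
target pIC50 range (default [5.02, 8.46], the span typical of such series).

What the benchmark does **not** establish: performance on real congeneric
series, where alignment error, conformational uncertainty, charge-model
error and activity-measurement noise all enter, and where Q² values of
0.4–0.6 are typical rather than 0.98. Substituents are random atom clouds,
not valid chemistry — the statistics under test are geometry- and
weight-driven, so chemical validity is irrelevant to what is being
verified. Plain SDF cannot carry the generator's per-atom weights, so
consumers that re-read the emitted SDF re-derive weights by rule and will
not see the planted functional exactly; recovery tests therefore run on
the in-memory series.

## Numerical choices and degenerate inputs

- Steric cap: per-entry infinities (grid point on an atom) are set to the
  cap before summation; the summed value is then capped, so the cap is
  exact at atom centers.
- Flagged electrostatic entries are mean-substituted from unflagged
  training rows; a column flagged everywhere becomes constant and is
  dropped by the variance filter.
- NIPALS declares rank exhaustion when the weight vector or score norm
  falls below 1e−12 and refuses component counts beyond `min(n−1, p)`.
- LOO folds whose remaining rows carry no descriptor variation (possible
  at small n when the left-out molecule was the only distinct one) predict
  the fold mean; folds whose rank falls short of a component count keep
  their highest-rank model. The per-fold component path is computed in a
  single NIPALS pass; equality with a literal per-count refit loop is
  tested at 1e−10.
- Constant activity vectors raise (the Q² denominator would be zero);
  perfect fits report SEE = 0 and F = inf explicitly; an empty test set
  omits R²_pred rather than reporting 0.
- Contour thresholding on an all-equal map warns and returns empty masks;
  if the two quantiles coincide, overlapping points are assigned to
  neither mask.
- 2:1 splitting stratifies by activity tertile (largest-remainder
  allocation keeps totals exact, e.g. 181 → 121/60); a seeded generator
  makes labels reproducible.

## Known limitations

- Donor/acceptor similarity uses heavy-atom positions, not projected
  interaction sites; maps near H-bonding groups are coarser than the
  original program's.
- The hydrophobic table is rule-based, not fitted; absolute hydrophobic
  field magnitudes are not comparable to implementations using proprietary
  tables (rankings within a series are).
- PEOE covers H, C, N, O, S, P, F, Cl, Br, I with hybridization-dependent
  parameters; other elements must arrive pre-charged via MOL2.
- The Lennard-Jones (ε, σ) table is a documented Tripos-style set, not a
  fitted force field; steric fields are comparable within, not across,
  parameterizations.
- Published headline statistics for specific datasets (e.g. Q² ≈ 0.5 on a
  181-compound antagonist series) are not reproducible without those exact
  prepared structures and the original program's undisclosed internals;
  this package's tests are property-based for exactly that reason.
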