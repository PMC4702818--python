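# Methods

This note records the models, conventions and numerical choices behind each
component, and what the synthetic fixtures do and do not establish about
real data.

## Map I/O

Maps are read and written in the CCP4-compatible MRC dialect: 1024-byte
header, optional extended header (skipped on read), voxel block in modes 0
(int8), 1 (int16) or 2 (float32); files are always written in mode 2.  On
load the volume is permuted to a canonical axis order — `data[ix, iy, iz]`
indexed by Cartesian x/y/z whatever the file's column/row/section mapping —
because every downstream computation assumes one convention.  Voxel size is
cell length divided by grid sampling, per axis; anisotropic voxels are
allowed in I/O and policed by the Fourier modules (max/min ratio ≤ 1.001).

Two origin dialects coexist in archived maps: the Å-valued ORIGIN header
words and the older integer start indices.  The Å origin wins when nonzero,
else origin = start × voxel size; the choice is recorded on the object.
Header statistics that disagree with the data (beyond float32 rounding)
produce a warning and are replaced by recomputed values: a validation tool
must describe the voxels actually present, not the header's claim.  `rms`
is the population standard deviation about the mean, matching the header
RMS word.  One consequence of the float32 header is that voxel sizes and
origins round-trip at single precision; a second write/read cycle is
bit-stable.

## Fourier Shell Correlation

Both volumes are transformed with a full FFT and reduced to a Hermitian
half-set: a Fourier voxel contributes only if its index tuple is
lexicographically ≤ that of its conjugate, so every conjugate pair is
counted once and `shell_counts` are counts of independent voxels.  Shells
are one reciprocal-grid step wide, `bin = round(|s|/Δs)` with
`Δs = 1/(N·voxel)`; the DC term is its own shell, reported with correlation
1 and excluded from resolution estimation; shells whose center exceeds
Nyquist (grid-corner voxels) are dropped.

Resolution is the first frequency, scanning upward, where the correlation
falls strictly below the criterion threshold, refined by linear
interpolation of (correlation − threshold) between adjacent shell centers;
the curve is never smoothed, keeping the estimate reproducible.  A curve
that never crosses yields "not reached" with the Nyquist bound attached.
The per-shell thresholds use the independent voxel count n of each shell:
half-bit `(0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n)` and 3σ `3/√(n/2)`.  On
small grids the innermost shells hold only a handful of independent voxels,
so the 3σ threshold exceeds 1 there and the criterion trips at the first
shell — visible in the worked example; this is a property of the criterion
at small n, not an artifact.  No symmetry-corrected effective counts, no
masking or phase-randomization corrections: both are out of scope.

Correctness is anchored by a direct-summation DFT oracle (explicit
exponential-matrix products and per-voxel shell loops, no FFT) that must
agree to 1e-9 on 8³–12³ grids, by the exact symmetries (argument order,
positive rescaling), and by the counting statistics of the null: for
independent white noise ≥95% of shells lie within |FSC| ≤ 3/√n.

## Half-map fixtures and the SNR closed form

`half_map_pair` adds independent white Gaussian noise fields (two streams
spawned from one seed, mirroring independent half-data reconstructions) to
a common signal.  With the unnormalized FFT, noise of variance σ² has
expected power N·σ² per Fourier voxel, so the designed per-shell SNR is
`P_signal(s)/(N·σ²)` with `P_signal` the signal's rotationally averaged
power spectrum, and the expected FSC is SNR/(SNR+1).  The standard test
conditions are a 12-residue ideal helix rendered as σ = 1.5 Å Gaussian
atoms on a 32³ grid of 1 Å voxels with noise σ = 0.1, which puts the SNR=1
crossing at 0.233 1/Å — comfortably mid-band.  Under these conditions the
mean measured FSC over seeds tracks the closed form within 0.05 per shell
and the fixed-0.5 crossing recovers the designed frequency within one shell
width in ≥90% of seeds.

What this shows: the estimator and its calibration are correct for
independent additive stationary noise.  What it does not show: behavior
under masking-induced correlation between half-maps, non-white noise,
symmetry averaging, or preferred orientation — none of which the generator
emulates.

## Map statistics

Histogram bins are equal-width over [min, max], right-open except the last
closed bin, so counts conserve the voxel count exactly; a constant map
degenerates to one occupied bin.  The rotational power spectrum shares the
FSC shell machinery (same unique-voxel set; conjugates have equal |F|², so
this equals the full-sphere mean) with the DC power reported separately.
Enclosed volume at a contour counts voxels **at or above** the level
(≥, not >) times the voxel volume — the recommended contour should enclose
its own level set — and is computed by binary search on the sorted
densities, making dense level grids cheap.  Indices are 0-based throughout;
central slices take plane ⌊N/2⌋.  The recommended contour itself is always
an input (it comes from the depositor), never derived.

## Model parsing and trace classification

PDB and mmCIF files are parsed with gemmi; the toolkit's own chain/residue/
atom containers keep the validation surface independent of the parser.
Alternate locations resolve to the highest-occupancy conformer (ties: first
in file order).  Polymer type is inferred from residue names by majority
(standard amino acids vs standard nucleotides).  A chain is `calpha-only`
iff protein with exactly one atom per residue, named CA; `p-only` iff
nucleic with exactly one P per residue; anything mixed is `none` and is
assessed with the full-atom checks only.

Consecutiveness is defined by residue numbering (successor number, or same
number with a new insertion code), never by distance: numbering gaps mark
unmodeled residues and the flanking pair is skipped, not flagged as a long
bond.

## Trace-geometry checks

*Cα–Cα*: a consecutive distance is an outlier iff it lies outside mean ± kσ
of **both** the cis and the trans reference modes (k defaults to 3).  The
two-window rule — rather than classifying the peptide's isomer first — is
the permissive reading: a distance compatible with either isomer is
acceptable.  The nearest class (smaller |z|) and its z-score are recorded.
All boundary comparisons are strict ("outside", "shorter than", "longer
than"), so a distance at exactly 3σ, 4.4 Å or 8.0 Å is not flagged.

*P–P*: flagged iff strictly < 4.4 Å or > 8.0 Å.

*Pseudo-Ramachandran*: for residue i with numbering-consecutive neighbors
i−1, i+1, i+2 all carrying CA, θᵢ = angle(CAᵢ₋₁, CAᵢ, CAᵢ₊₁) ∈ [0°, 180°]
and ηᵢ = dihedral(CAᵢ₋₁, CAᵢ, CAᵢ₊₁, CAᵢ₊₂) ∈ (−180°, 180°]; the pair is
assigned to residue i (the second of the four — one convention had to be
fixed; it is echoed in the report output).  The reference is a 5°×5° grid
of frequencies (θ bins right-open, η bins left-open to keep +180° in the
last bin), looked up nearest-bin; a residue is an outlier when its bin
frequency is below a cutoff chosen so that bins strictly below it hold at
most a stated tail mass (default 0.05%) of the reference.

Reference distributions are versioned inputs with a JSON schema
(means/sigmas, P–P bounds, flattened grid + bin metadata).  The built-in
defaults are **synthetic**: community-standard cis/trans location
parameters and a smooth two-component (helical + extended) grid with a
uniform floor, generated programmatically — adequate for testing,
demonstration and threshold semantics, but not a substitute for
archive-derived statistics, which users can load from their own files.

*Close contacts*: pairs closer than r₁ + r₂ − 0.4 Å (Bondi-style radii,
tolerance configurable), excluding same-residue pairs, peptide C–N and
nucleic O3'–P bonds across consecutive residues, and consecutive trace
CA–CA / P–P pseudo-bonds.  Candidates come from a k-d tree cut at the
largest possible clash distance; the result is tested equal to an all-pairs
oracle.  Unknown elements are skipped with a logged warning rather than
failing the run.

*Atom inclusion*: density at each atom position by trilinear interpolation
(exact at voxel centers; nearest-voxel lookup available as an option),
included iff ≥ contour.  The denominator is all atoms; atoms outside the
grid count as excluded and are reported.  Inclusion is non-increasing in
the contour level by construction.

## Report

The JSON document is schema-versioned (pydantic models are the schema) and
deterministic: fixed inputs give byte-identical output, with the provenance
timestamp caller-supplied (empty by default) so reproducibility is the
default rather than an afterthought.  Sections that fail record their error
and the report is still produced.  Percentile sliders use mid-rank scoring,
100·(worse + 0.5·equal)/n, which is monotone and direction-symmetric;
reference populations ship as small sample files and the built-in test
populations are synthetic — archive-scale percentile curation is explicitly
out of scope, as are populations stratified by resolution.

## Problem sizes

The test and acceptance computations run on 8³–32³ grids and chains of 2–20
residues: large enough that shell statistics, interpolation and the
k-d-tree path are all exercised in their asymptotic regime, small enough
that the full suite completes in seconds.  Threshold recovery bisections
evaluate the checks a dozen times each at tolerance 0.001.

## Known limitations

- No masking/phase-randomization FSC corrections, map-vs-model FSC, or
  symmetry-aware effective voxel counts.
- Full-atom covalent geometry (bonds/angles/torsions/rotamers/ligands) is
  not validated here; only close contacts plus the trace checks.
- The shipped reference distributions and slider populations are synthetic
  stand-ins; production use should supply archive-derived files.
- Shell binning and interpolation conventions are fixed and documented but
  not guaranteed to agree numerically with any particular external FSC
  implementation.
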