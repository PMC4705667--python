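# Methods

## Model and assumptions

`methylclash` treats protein and DNA as rigid bodies and asks whether a
methyl group, added to a base in the geometry the complex was crystallized
in, collides with its surroundings. Three simplifications define the scope:

* **Implicit hydrogens.** Crystal structures at typical resolution do not
  resolve hydrogens, so every heavy atom carries a united-atom van der Waals
  radius that absorbs its bonded hydrogens. The grafted methyl is a single
  pseudo-atom of radius *R* = 2.0 Å (an aliphatic CH₃, like the thymine
  methyl).
* **Coordinate-error allowance.** Crystallographic coordinate errors are
  mostly below 0.1 Å, so every measured distance *D* is inflated to
  *d* = *D* + ε with ε = 0.1 Å by default before any overlap is computed.
  Raising ε (the robustness sweep runs 0.1–0.4 Å) is also a crude proxy for
  adaptive fit, since it forgives small overlaps first.
* **No relaxation.** No energy minimization, no hydrogen placement, no
  side-chain repacking. A clash score is a property of the deposited
  coordinates plus the idealized methyl, nothing else.

## Structure model

Structures load from PDB or mmCIF via gemmi (first model only). Hydrogens
and deuteriums are stripped on input. Alternate conformers are retained with
their labels; scoring uses the highest-occupancy conformer per atom, ties
broken by altloc sort order (the common crystallographic convention).
Waters, metal ions and non-nucleic ligands are excluded from the clash
partner set by default (`ClashParams.include_excluded` re-admits them with
the 2.0 Å fallback radius). Strand identity is chain identity: "opposite
strand" means a different DNA chain, so a single-chain hairpin scores as
same-strand throughout (logged at load time). Symmetry mates are never
generated; only deposited coordinates are used. Protein N, CA, C, O — plus
Cβ, whose position is fixed by the backbone, and the terminal OXT — count as
main chain; everything else on an amino acid is side chain.

## Van der Waals radii

The table (`data/vdw_radii.tsv`, overridable) assigns radii by ordered
(residue, atom) rules with an "all other atoms" fallback of 2.0 Å.
Highlights and their chemical logic: carboxylate oxygens 1.5 Å (compromise
between carbonyl 1.4 and hydroxyl 1.6); amide O/N of Asn/Gln 1.6 Å (averaged
CONH₂); aromatic/base ring atoms 1.7 Å as balls (no in-plane ellipsoids —
clash geometry is not analysed, so the smaller radius is the conservative
choice); exocyclic amines like the arginine guanidino group 1.7 Å; aliphatic
CH/CH₂/CH₃ 2.0 Å; sulfur 1.8 Å; sugar/phosphate and exocyclic base oxygens
1.4 Å like the main-chain carbonyl oxygen; phosphorus 1.8 Å. The protein
C-terminal carboxylate is treated as COOH (OXT 1.5 Å), the N-terminus like a
Lys amine (2.0 Å via the main-chain N rule at 1.7 — see limitations),
selenomethionine selenium as sulfur (1.8 Å). Both DA/DC/DG/DT and
single-letter nucleotide codes are accepted.

## Methyl templates and grafting

Templates are idealized planar bases (chemical-component-dictionary internal
geometry projected into the exact ring plane) with the methyl carbon placed
in-plane:

* **m5C** — at C5 along the external bisector of C4–C5–C6, bond 1.50 Å
  (aromatic C–CH₃). Its position is unique; *cis/trans* does not apply.
* **m6A** — at N6, 1.47 Å, 120° to the N6–C6 bond, on the side closer to N7
  (*trans*, Hoogsteen).
* **m4C** — at N4, 1.47 Å, 120° to the N4–C4 bond, on the side closer to C5
  (*trans*).

These bond parameters are standard small-molecule values and are the fixed
template constants of the package. Superposition onto the target base uses
ring atoms only (pyrimidine N1…C6; purine N1…N9) — never sugar or phosphate
atoms, and not the exocyclic substituents, which keeps the fit robust to
tautomer naming. The rigid transform is the proper-rotation least-squares
fit (Kabsch via scipy); the reported RMSD is recomputed from the moved
coordinates because the solver's internal residual loses precision to
cancellation near exact fits. The *cis* rotamer is produced by mirroring the
template methyl across the attachment–anchor line within the base plane,
which preserves bond length and attachment angle exactly. Grafting a methyl
onto an incompatible base (m6A on anything but adenine, m5C/m4C on anything
but cytosine) is an error, as is a target missing ring atoms (the error
names them).

## Clash scoring

With partner radius *r* and *d* = *D* + ε:

* Δd = *R* + *r* − *d*; pairs with Δd ≤ 0 are not clashes and are not stored.
* ΔV is the two-sphere lens volume
  π(R+r−d)²(d²+2dr−3r²+2dR+6rR−3R²)/(12d) in the partial-overlap regime
  |R−r| < d < R+r. For d ≤ |R−r| the printed expression is no longer the
  intersection volume, so the containment branch returns the smaller
  sphere's volume (4/3)πr³ — the lens expression reaches exactly this value
  at d = |R−r|, so the function is continuous, and d = 0 never divides by
  zero.

Candidate partners are all non-hydrogen, non-excluded atoms within the
neighbour cutoff (5.0 Å default, ≥ the maximal R+r = 4.0 Å; an infinite
cutoff reproduces the accelerated result exactly). Atoms within three bonds
of the methyl carbon in the parent base are excluded — the standard
1-2/1-3/1-4 steric convention for a substituent that replaces a hydrogen:
{C5, C4, C6, N1, N3, N4} for m5C, {N6, C6, N1, C5} for m6A,
{N4, C4, N3, C5} for m4C. The rest of the parent nucleotide and all other
atoms remain eligible, so genuine same-strand DNA contacts (including the
intrinsic methyl–N7 proximity of *trans* m6A) are counted. When both strands
are methylated, the partner strand's grafted methyl is an eligible partner
(manifest-controlled); the methyl–methyl pair appears in each methyl's clash
list but should be counted once in any total over methyls.

Per-methyl summaries carry max/sum of Δd and ΔV, the number of contacts and
of distinct contacted residues, and partitions by partner category and
element.

## Dataset analysis

Effect-group labels (cognate protective / non-cognate tolerated /
non-cognate protective) are external experimental annotations supplied in
the manifest; they are never inferred from scores. Enzymes get equal
statistical weight: per-methyl scores are averaged over asymmetric-unit
copies and (policy-dependent) over strands. Group comparisons use the
two-sided Wilcoxon rank-sum test — exact enumeration when both groups have
≤ 10 tie-free observations, otherwise the tie-corrected normal approximation
without continuity correction (so identical groups give p = 1 exactly).
Shapiro–Wilk normality p-values are reported per group and measure; a
constant sample is an error rather than a p-value. ROC curves group tied
scores and AUC is the trapezoid integral.

The threshold classifiers use **protein-only** scores (omitting DNA clashes
sharpens the protective/tolerated distinction) computed per strand with ASU
copies averaged; an enzyme protected on both strands is judged by its
stronger strand. Default thresholds: most severe distance clash > 1.1 Å, or
cumulative volume overlap > 47.7 Å³ — strictly greater, so a score exactly
at the threshold is called tolerated. ROC observations are enzyme-level by
default (`roc_level="strand"` pools per-strand scores instead). Positives
are cognate-protective enzymes, negatives tolerated ones; the non-cognate
protective group is held out as validation. No multiple-testing correction
is applied: raw p-values are reported.

The ε-allowance sweep rescoring is pure arithmetic: the model records all
near contacts (distance and radius) once at construction, so
`allowance_sweep` re-thresholds them per ε without touching the structures.

## Synthetic data: what it emulates, and what it does not

The generator produces three kinds of fixtures, all deterministic under a
seed and requiring no input files:

* **Ideal duplexes** — exactly planar idealized Watson–Crick pairs
  (pair geometry solved against consensus heavy-atom hydrogen-bond distances
  under a pseudo-dyad constraint: A:T N1–N3 2.82 Å; G:C N1–N3 2.90 Å)
  stacked at 3.38 Å rise / 36° twist. Base atoms and C1′ only: no backbone,
  no sugar pucker, no sequence-dependent deformation.
* **Probe environments** — a duplex plus single protein-like atoms placed at
  exact distances from the pre-computed methyl position, so downstream clash
  scores are known by construction. Probes are emitted as single-atom
  amino-acid residues (CB/N/O/SG) so the standard radius and
  partner-category rules apply to them.
* **A full synthetic study** — 78 methylation instances in the published
  group composition (21 cognate protective: 5 m5C/7 m6A/9 m4C; 22 tolerated:
  14/8/0; 35 non-cognate protective: 20/6/9). Most-severe clashes are drawn
  around the reported group statistics (protective ≈ 1.7 Å mean / 1.8 Å
  median, N-linked harder than C5; tolerated ≈ 0.6/0.7 Å), with the
  dataset's five reported exceptions encoded explicitly: two weakly clashing
  protective methyls (0.4 and 0.7 Å, uncrowded) and three severely clashing
  tolerated methyls (2.2 and 1.7 Å on one shared enzyme — two adenines of a
  single target sequence — plus 1.5 Å). Secondary-contact crowding scales
  with severity (Poisson mean 3 + 12·Δd_max, extras uniform in
  [0.5·Δd_max, Δd_max]), which puts protective cumulative volume overlaps on
  the 47.7 Å³ decision scale; a few sub-threshold near contacts are added so
  the allowance sweep has contacts to eliminate.

Passing tests on these fixtures demonstrates that the geometry, scoring and
statistics machinery is correct and that the advertised operating points
follow from the stated group characteristics. It does **not** demonstrate
anything about real crystal structures: the generator has no real protein
environments, no correlated contact geometry, no crystal-packing artifacts,
and its clash-severity distributions are a model of the reported statistics,
not a re-measurement. A note on internal consistency: a most-severe distance
clash of ~1.7 Å corresponds to a single lens volume of only ~6–8 Å³, so
cumulative volumes above 47.7 Å³ require many secondary contacts; the
generator therefore realises most-severe/cumulative volume ratios of
~0.10–0.15 rather than ~1/3.

## Numerical choices

* Superposition RMSD recomputed from moved coordinates (see above);
  transforms are always proper rotations (det +1).
* ΔV containment branch as described; the boundary d = R+r returns exactly 0.
* Altloc ties break by label sort; classifier boundaries are strict.
* Monte-Carlo overlap oracle: hit-or-miss sampling in the bounding cube of
  the smaller sphere, unbiased with binomial standard error; formula checks
  use a 3-standard-error band on a grid of radii and separations
  (2×10⁵ samples per grid point; one spot check at 10⁷).
* Problem sizes: the test suite and the acceptance script run the full
  synthetic study (78 instances, ~2,700 contacts), duplexes of 2–6 bp, and
  20 random-transform recovery trials; these sizes make every check exact or
  statistically stable while keeping a full run in seconds.

## Known limitations

* Rigid-body scoring: adaptive fit is only mimicked by the ε sweep, and
  hydrogen-bond losses upon methylation are invisible — a methylation can be
  protective with almost no clash (disrupted contacts), or tolerated despite
  a large one (flexible periphery, or an N-methyl that can flip to *cis*).
  The *cis* override covers the latter case but must be requested explicitly
  in the manifest.
* N-terminal amine radius falls to the main-chain N rule (1.7 Å) rather than
  a dedicated 2.0 Å NH₃⁺ rule; rare chemistries (phosphorothioates, modified
  bases beyond the grafted methyl) take the 2.0 Å fallback.
* The duplex builder is a fixture generator, not a DNA model: real B-DNA
  backbone atoms, groove widths and deformability are absent.
* Biological-assembly reconstruction, NMR ensembles beyond the first model,
  and crystallographic error estimation are out of scope.
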