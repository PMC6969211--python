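# Methods

`agcphos` re-implements, as a tested pipeline, a comparative and structural
analysis of the two regulatory phospho-sites of AGC kinases: the
activation-loop (AL) site inside the DFG..APE activation segment and the
hydrophobic-motif (HM) site on the C-terminal tail.  The scientific
question it operationalises: phosphomimetic substitutions (Asp/Glu) are
common at the HM but essentially never occur at the AL, and the structural
reason is that an aspartate carboxylate cannot reach the full network of
three basic residues that the AL phosphate coordinates.

## Sequence analysis

**Activation segment.**  The segment is located as the leftmost DFG whose
nearest downstream APE-like terminator yields an inclusive span of 20–60
residues.  Because many AGC kinases deviate from a literal Ala-Pro-Glu, the
terminator defaults to the degenerate pattern `[APSG][PIV]E` (configurable).
Known family segment lengths run from 25 (PKAα) to 43 (MAST1) residues; the
20–60 band brackets that range without accepting spurious matches.  A
kinase with no accepted segment has no conserved activation loop and its AL
call is *absent*.

**AL site.**  Inside the segment, the consensus `S/T-x-x-G-T` is searched
right-to-left (the AL phospho-site sits near the P+1 loop, adjacent to the
APE end), so the rightmost match wins.  When the consensus fails — which is
precisely what happens when the site carries a substituted residue — the
classifier falls back to the multiple-alignment column homologous to the
reference site (RSK2 Ser227) and classifies whatever residue occupies it.
The fallback is applied only when the kinase has an accepted segment;
without a segment there is no activation loop to classify.

**HM site.**  The last 60 tail residues (configurable) are scanned for
`F-x-x-[FY]-z-[FY]`, with z the phospho-position.  A bare `F-x-x-[FY]` head
at the extreme C-terminus with no complete motif is reported as a
*truncated* HM (the PKA situation) rather than silently merged into
"other"; this truncation rule is a documented choice, not an established
convention.

**Residue states.**  S/T → phosphorylatable, D/E → phosphomimetic, all
other residues (including X) → other.  Basic means Arg/Lys/His: histidine
counts because in PKA the αC-helix position homologous to RSK2 Arg114 is
His87 and is treated as a positive site.

**Triad mapping.**  The three phosphate-coordinating positions (RSK2
Arg114 on the αC-helix, Arg192 in the catalytic loop, Lys216 just after
DFG) are projected onto every kinase through the alignment columns of the
reference row's ungapped positions.  Internally all coordinates are
0-based; every report prints 1-based numbers so residue names match the
literature (Ser227, Arg114, …).

**Co-occurrence.**  Euler overlaps are exact set counts over predicate
pairs (default: phosphorylatable AL × basic residue at a triad site).  The
association is quantified with a two-sided Fisher exact test written out
from the hypergeometric mass: all tables with the observed margins whose
probability does not exceed the observed table's are summed (a 1e-9
relative slack guards the comparison against floating-point rounding).

**Phylogeny.**  Pairwise distances come from the alignment either as
p-distance (mismatch fraction over columns where neither row is gapped; a
pair with no comparable column is an error) or as a scoredist-style
`−ln` of BLOSUM62 similarity normalised between the uniform-background
expectation and the mean self-score, clamped at 3.0 substitutions/site when
the normalised similarity is non-positive.  Trees are built with canonical
Saitou–Nei neighbor joining: Q-criterion joins, Saitou–Nei branch lengths,
reduction `d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`, closing the final three-taxon
star in closed form.  Ties in Q are broken toward the lexicographically
smallest taxon-name pair; negative intermediate branch lengths are clamped
to zero with the deficit moved to the sibling edge, preserving the path
length through the joined pair.  NJ is exact on additive matrices, which is
what the acceptance suite exercises; the published kinome tree itself is
not a target because it depends on the upstream aligner.

## Structural analysis

**PDB handling.**  A fixed-width ATOM/HETATM parser (phospho-serine, SEP,
is routinely deposited as HETATM) splits MODEL/ENDMDL blocks into models;
a multi-model file doubles as the trajectory format.  Alternate locations
keep the highest-occupancy conformer (ties: altloc A); hydrogens are
dropped because the analysis is defined on heavy atoms.  Malformed lines
fail with their line number.

**Superposition.**  Kabsch: SVD of the cross-covariance with determinant
sign correction, so reflections are never returned.  Cross-structure
comparisons use matched CA pairs (from a sequence alignment of the chains).

**Salt bridges.**  For a SEP/ASP/GLU centre, the acidic oxygens
(O1P/O2P/O3P/OG, OD1/OD2, OE1/OE2) are tested against the basic nitrogens
(Arg NE/NH1/NH2, Lys NZ, His ND1/NE2); one contact per basic residue at the
minimum O–N distance, reported when ≤ cutoff.  The default cutoff of 4.0 Å
between charged-group heavy atoms is chosen to separate an interacting
carboxylate–guanidinium pair (~3.9 Å) from a non-interacting one (~5.2 Å);
direct phosphate bridges sit near 2.2–3.2 Å.

**Ser→Asp substitution.**  The backbone and CB stay fixed; OG and
phosphate atoms are removed; CG/OD1/OD2 are rebuilt with ideal internal
geometry (CB–CG 1.516 Å, CG–OD 1.249 Å, angles 113.4°/118.4°) over a
deterministic rotamer grid, χ1 ∈ {−60°, 60°, 180°} × χ2 ∈ −90°…90° in 30°
steps.  Candidates score −10 per heavy-atom clash (< 2.8 Å to any atom
outside the residue) and +1 per carboxylate oxygen within 4.0 Å of a basic
nitrogen; the best score wins, ties broken by grid order.  The library and
weights are fixed documented constants — the goal is a reproducible "most
favourable rotamer", not a force-field minimum.

**Trajectory post-processing.**  The RMSD trace superposes each frame on
the reference over the selection (default CA) and reports the residual
RMSD.  RMSF superposes all frames on the mean structure, recomputes the
mean, and repeats for two refinement passes (the mean-structure convention,
not frame 0), then reports per-residue `sqrt(mean_t |r_i(t) − r̄_i|²)`.

## Synthetic data: what it emulates, and what it does not

The generators produce every input with re-measurable ground truth:

- `gen_kinase_family` plants a 290-residue template domain (DFG at 171,
  APE ending at 199, AL site at 191 with the G/T anchor, HM at 285,
  triad columns at 86/161/176, 1-based).  State counts and the number of
  basic triad residues within the phospho-AL and non-phospho-AL groups are
  allocated by largest-remainder rounding and shuffled by seed, so the
  default parameters reproduce the observed 61-kinase composition exactly:
  43 phosphorylatable AL / 17 other / 1 absent; 32 phosphorylatable HM /
  5 phosphomimetic / 16 other / 8 absent; a basic αC residue in 25 of the
  43 phospho-AL kinases and nowhere else; the catalytic-loop site basic in
  all 61.  Substitution noise (default rate 0.02) hits non-motif columns
  only and is drawn from an alphabet without D/E/F/G/P/S/T/Y, so no noise
  level can assemble a spurious motif; the MSA is indel-free by design.
  Consequences: perfect classification on these families shows the motif
  engine implements its rules exactly, not that real kinomes — with
  indels, divergent motifs and alignment error — would classify perfectly.
- `gen_structure_pair` draws a uniform point cloud and applies a known
  rotation/translation plus optional isotropic jitter σ; the optimal
  superposition RMSD approaches σ√3.
- `gen_phospho_site_structure` places basic side-chain fragments on
  separated outward directions so each planted minimum O–N distance is
  exact to 1e-6 Å (the closest-approach oxygen is the one extremal along
  the placement direction, which guarantees the minimum).
- `gen_trajectory` adds per-residue isotropic Gaussian jitter (expected
  RMSF σ_i√3) and optionally a global rigid wobble that superposition must
  remove.  Gaussian jitter rather than correlated dynamics is deliberate:
  the closed form is exact, and only the post-processing contract — not
  molecular dynamics itself — is being tested.

## Numerical and scale choices

- RMSF recovery checks use 2000 frames and ≥ 60 residues: the relative
  sampling error is ~1/√(2T) ≈ 1.6% and the rigid-body absorption of the
  superposition is ~√(1−6/3n) ≈ 1.7%, both comfortably inside the 5% band.
- NJ exactness is asserted to 1e-9 on path-length matrices of random
  additive trees (5–12 taxa, internal edges ≥ 0.3).
- Kabsch is cross-checked against multi-start Nelder–Mead minimisation
  over rotation vectors to 1e-6.
- Newick is written with 6-decimal branch lengths; round-trip checks allow
  1e-5 on path lengths accordingly.
- Fisher's test enumerates the full hypergeometric support; fine for the
  kinome-scale tables it is used on (n ≤ a few hundred).

## Known limitations

- The published per-kinase counts and the deposited-structure distances
  (crystal pSer227 contacts, the S227D rotamer distances, the RSK2/Akt2
  CA RMSD) can only be recomputed when the external kinome sequences and
  PDB entries 4NW5/1O6K are available locally under `data/external/`; the
  corresponding acceptance tests run the real computation and fail
  otherwise.
- Multi-nanosecond dynamics (RMSD plateau behaviour, post-simulation
  H-bond distances) are out of scope; only trajectory post-processing is
  implemented and validated.
- The HM truncation rule and the degenerate APE terminator are documented
  interpretations where no exact published criterion exists.
- Alignments are consumed, never built; classification quality on real
  data inherits the upstream aligner's quality.
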