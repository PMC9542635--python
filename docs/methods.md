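# Methods

## The empirical interface potential

The scan needs a binding score that is cheap, deterministic and pairwise
additive, so that truncating a side chain has an exactly computable effect.
`capscan` uses a heavy-atom class potential. Every atom carries a subset of
five physicochemical classes — nonpolar (all C and S), donor, acceptor,
positive, negative — from a fixed per-residue lookup table (backbone N is a
donor, backbone O/OXT acceptors, OXT negative; side-chain membership follows
standard chemistry, e.g. Arg NE/NH1/NH2 donor+positive, Asp OD1/OD2
acceptor+negative, Ser OG donor+acceptor, Cys SG donor+nonpolar, Met SD
acceptor+nonpolar). Non-standard residues fall back to element rules.

For a cross-partner pair at distance d (Å), with ramp(d; on, off) = 1 below
`on`, 0 above `off`, linear between:

| term | condition | energy (kJ/mol) | defaults |
|---|---|---|---|
| steric | d < d_clash | +k_clash·(d_clash−d)/d_clash | 2.5 Å, 25 |
| dispersion | both nonpolar | −k_np·ramp(d; np_on, np_off) | 0.4, (3.4, 6.0) Å |
| hydrogen bond | donor↔acceptor | −k_hb·ramp(d; hb_on, hb_off) | 4.0, (2.6, 3.6) Å |
| charge | opposite / like | ∓k_q·ramp(d; q_on, q_off) | 8.0, (2.8, 5.0) Å |

All applicable terms sum; everything is zero at or beyond the 8 Å global
cutoff. The magnitudes are ordered charge > hydrogen bond > dispersion,
which is the physically sensible ordering for desolvated interface contacts
and makes designed test fixtures discriminate the three contact types
cleanly. The parameters are this package's own fully specified surrogate
scoring function: published empirical scan servers use proprietary parameter
sets, and no attempt is made to reproduce any particular one, so absolute
ΔΔG values are not comparable across programs — only the ranking machinery
and its exactness guarantees are asserted.

## Alanine scanning over an ensemble

ΔΔG(R) = ΔG(R truncated beyond Cβ) − ΔG(wild type); positive values mean the
residue stabilises binding. Gly and Ala are not scannable (reported with
ΔΔG 0, unranked); Pro is truncated like any other residue; backbone atoms
and Cβ are never removed; no rebuilding or relaxation after truncation —
conformational response is deliberately out of scope. Because the potential
is pairwise additive, ΔΔG equals minus the summed pair energies of the
removed atoms; the test suite verifies this against a naive double loop on
literally truncated structures to 1e-9 kJ/mol.

Over an M-model ensemble the per-residue ΔΔGs are averaged (sample SD
reported, exactly 0 when all models agree), reflecting the practice of
feeding multiple conformations — e.g. final frames of independent MD runs —
to a scan rather than one crystal pose. `w_polar` ∈ (0, 1] scales the mean
for Asp/Glu/Arg/Lys/His before ranking (default 1.0, i.e. off; 0.5 mirrors
the DERKH down-weighting some scoring schemes apply, a correction that can
itself be too severe). Ranking is by descending weighted ΔΔG, ties broken by
residue identifier.

## Structure handling

gemmi parses PDB and mmCIF. Hydrogens, waters, ions and non-amino-acid
heteroatoms are dropped; altloc duplicates resolve to the highest occupancy
(ties: first in file). Author numbering with insertion codes is kept
throughout so residue labels match the literature on a given binder. The
atom inventory must be identical across models — a hard error otherwise,
since per-model ΔΔGs would not be comparable.

## Interface annotation

Interface residues: any cross-partner heavy-atom pair within 5 Å (default).
Hydrogen-bond proxy: donor↔acceptor heavy atoms within 3.5 Å, no angle term
(hydrogens are unavailable by design). Cation-π: aromatic ring centroid
(Tyr/Phe six-ring, Trp six-ring, His five-ring) within 6 Å of an Arg
guanidinium centroid with interplanar angle ≤ 30° (parallel packing), or of
Lys NZ by distance alone; the numeric criteria are exposed defaults, since
no community consensus values exist. Annotations carry persistence — the
fraction of models containing the contact — plus the mean over those models
of the minimum qualifying distance, and the first model index containing it.

## Affinity bridge, additivity and the planner

ΔΔG = RT ln(fold), R = 0.008314 kJ/mol/K, T default 298.15 K. Variant Kds
assume additivity on the free-energy scale,
Kd = Kd_wt·exp(ΣΔΔG/RT); the planner uses the weighted (DERKH-corrected)
ΔΔG estimates, which equal the plain means at the default w_polar = 1. The
caging effect enters as a user-supplied fold-change (defaults 420 for
nitropiperonyl tyrosine, ~10,000 for ortho-nitrobenzyl tyrosine) rather than
a structural model: caging groups can form their own contacts (e.g. a stable
cation-π with an interface arginine), so their effect is context-dependent
and best taken from measurement.

`plan_switch` enumerates all secondary-mutation subsets up to k_max
(default 2, the practically explored regime of single and double secondary
mutants). Verdicts: `pass` iff caged-state antigen occupancy ≤ θ_off (0.05)
and uncaged occupancy ≥ θ_on (0.5); when both states fail, `fail_off` is
reported, because residual caged binding is the failure mode the workflow
exists to eliminate — `fail_on` marks over-weakened designs that would stay
cytoplasmic even after uncaging. Non-tyrosine cage sites are refused unless
forced (the supported photocage chemistry is tyrosine-based). Plans whose
secondary residues share contact atoms are flagged (`additivity_warning`)
when an ensemble is supplied, since free-energy additivity is least reliable
for overlapping contact sets. Additivity itself is exact within this
potential only for residues with disjoint contact atoms (tested); real
double mutants can deviate, and the planner reports but cannot resolve such
discordance.

## Occupancy model of the localisation read-out

The antigen is treated as fully nuclear and immobile (an NLS-anchored
construct); the binder (~40 kDa fusion) diffuses freely across the nuclear
envelope, so its free concentration is uniform. Mass conservation per total
cell volume gives a quadratic in the free binder concentration x,

    x² + (Kd + φ·A − N)x − Kd·N = 0,

solved in closed form with the numerically stable root and a bisection
fallback (relative tolerance 1e-10); the bound complex A·x/(Kd+x) is
confined to the nucleus. N/C = (x + complex + bg)/(x + bg); the optional
background offset bg (default 0) caps the ratio, as measured ratios saturate
in real images (autofluorescence, out-of-focus light). No attempt is made to
fit measured in-vivo N/C values: intracellular binder and antigen
concentrations are unknown, so predictions are scenario-based. Kinetics,
transport rates and macromolecular crowding are out of scope.

## ELISA fitting

y = Bmax·x/(Kd+x), plain one-site with no nonspecific/background term,
fitted by bounded least squares (scipy `curve_fit`, tolerances 1e-10,
≤10⁴ evaluations). Initialisation: Bmax₀ = max(y), Kd₀ = concentration at
half-maximal mean response by linear interpolation. Replicates are fitted
jointly with equal weights. Degenerate inputs (fewer than 4 distinct
concentrations, flat responses) are errors, not NaNs. Fitted Kd is exactly
scale-equivariant in concentration units.

## N/C quantification

Cytoplasm = cell mask minus nucleus mask, with no erosion ring — the
simplest deterministic ROI convention, chosen because assay protocols rarely
specify one. Background (a constant, the image mode, or the median outside
all cells — the default) is subtracted with a floor at 0; each nucleus label
must lie within exactly one cell. 2-D single-channel only. The ratio is
invariant under multiplicative gain applied after background subtraction.

## Synthetic data

`generate_complex_ensemble` builds two-chain complexes in which each
designed contact occupies its own lane (40 Å apart): the controlled atom
pair sits at its designed distance exactly, and every other cross-chain atom
pair is kept beyond the 8 Å cutoff by anchoring spectator atoms at ±8.5 Å
along the contact axis. Because a ContactSpec places a chosen *subset* of a
residue's heavy atoms, bonds to skipped atoms are stretched; the generator
deliberately trades local geometric realism for exact, hand-computable
energetics (e.g. a Lys NZ–Asp OD1 salt bridge at 3.0 Å scores
2.4 + 8·(2/2.2) = 9.67 kJ/mol on truncation). One controlled pair per
contact is supported; conflicting or multiple distance constraints on a
residue pair are rejected as infeasible. Per-model isotropic Gaussian jitter
(typically 0.2 Å) emulates the pose spread of an MD ensemble — it reproduces
ensemble variance and rank stability, not physical dynamics, so passing
tests demonstrate the machinery, not predictive accuracy on real complexes.

The ELISA generator draws Gaussian noise around the true curve (floored at
0), default 8 log-spaced concentrations over 0.01–100×Kd with 3 replicates
and 5% noise — a realistic plate-assay regime. The synthetic cell is a pair
of concentric discs with optional Gaussian or Poisson noise; Poisson at the
default ~100-count intensities recovers the true ratio to well under 5% for
nuclei of ≥500 pixels.

## Problem sizes and determinism

Designed fixtures use 20-model ensembles (~36 atoms each), ELISA recovery
uses 200 simulations per affinity at four measured Kd values, and the
Poisson N/C check uses 50 synthetic cells; these sizes make every guarantee
checkable in seconds while keeping Monte-Carlo estimates stable. All
generators take explicit seeds; the acceptance script derives every stream
from its single `--seed`.

## Known limitations

- The potential is a surrogate: absolute ΔΔG values are not transferable to
  other scoring functions, and no external benchmark on published complexes
  is bundled (validating hot-spot recovery on real crystal structures
  requires downloading them and is left to the user).
- No conformational relaxation after truncation; rigid ensembles only.
- Additivity of ΔΔG across mutations is an assumption, flagged but not
  corrected when contact sets overlap.
- The occupancy model ignores kinetics, transport and crowding; the
  background term is a phenomenological cap, not a calibrated optical model.
- Hydrogen-bond detection is distance-only; trajectory formats (DCD/XTC) and
  3-D image stacks are unsupported.
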