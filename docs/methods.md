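# Methods

This note documents the models and procedures `abxspace` implements,
the defaults it ships, the design decisions that were genuinely open,
and what its tests do and do not demonstrate.

## Activity labelling

Each assay record carries a value, units, a relation qualifier and an
assay class (growth-inhibition vs biochemical). Labelling maps the
record onto `{A, SA, I}` using per-class concentration bands:

| assay class   | active (A)  | slightly active (SA) | inactive (I) |
|---------------|-------------|----------------------|--------------|
| antibacterial | ≤ 8 µg/ml   | (8, 32] µg/ml        | > 32 µg/ml   |
| biochemical   | ≤ 10 µM     | (10, 100] µM         | > 100 µM     |

The 8 µg/ml MIC cutoff is the conventional activity threshold in
antibacterial screening; the remaining bands are typical
active/inactive project decisions and are fully configurable
(`FilterSpec`). Units are normalized by a case-insensitive alias table
(µg/ml, ug/mL, mg/L → µg/ml; µM, umol/l → µM); conversion between the
two scales uses `µM = 1000 · (µg/ml) / MW` with the desalted parent's
molecular weight. Anything else is counted and excluded — the readers
never silently drop a row (retained + rejected + excluded = input).

Censored values assert only what they prove: an upper bound at or
below the active cutoff proves A, a lower bound above the
slightly-active cutoff proves I, and a bound straddling a band
boundary decides nothing (the record is dropped with a counter). A
missing relation is read as `=`, the most common convention in
activity exports. Duplicate (compound, assay) measurements aggregate
to the best label (A > SA > I), matching the existential form of the
active definition; worst/majority aggregation is available.

## Set construction

Over a compound's tested entries in one matrix:
*active* ⇔ at least one A and no I; *inactive* ⇔ at least one tested
entry and all I; everything else (only SA, or an A/I conflict) is
indeterminate, and an untested compound is simply absent. The eight
sets follow: AA/AI and BA/BI per matrix, BAAA = AA ∩ BA, and BAAI
defined in relaxed form — biochemically active with *no* antibacterial
record at all (the strict "active in BA and inactive in AA" variant
yields almost nothing, because few compounds carry only inactive
antibacterial records). MAD/MOD come from the approval annotations
regardless of assay data. The classifier is verified exhaustively
against a literal evaluation of the quantified definitions on all 256
label vectors of length ≤ 4, and the set algebra
(AA ∩ AI = ∅, BAAA ⊆ AA ∩ BA, BAAI ∩ AA = ∅, MAD ∩ MOD = ∅) is
property-tested on randomized matrices.

## Standardization

Three ordered steps, then charge-class assignment:

1. **Representation normalization** — RDKit's normalizer gives one
   canonical form for aromatic systems and for drawing variants such
   as pentavalent vs charge-separated nitro groups.
2. **Salt stripping** — components on a ~35-entry editable salt list
   (`data/salts.smi`: halides, alkali/alkaline-earth cations, sulfate,
   nitrate, acetate, tosylate, common organic acids, water, ammonia)
   are removed; if several components remain the one with most heavy
   atoms is kept (ties broken by canonical SMILES). If *every*
   component is a listed salt the largest is kept and flagged rather
   than returning an empty structure.
3. **Ionization at pH 7.4** — reversible charges are first neutralized
   (so the step is idempotent), then a data-driven SMARTS rule table
   (`data/ionization_rules.tsv`, 10 rules with representative pKas)
   deprotonates carboxylic/sulfonic/phosphonic acids, tetrazoles and
   acyl sulfonamides, and protonates aliphatic amines, amidines and
   guanidines. When two rules claim the same atom the first rule in
   the table wins (guanidine before amidine before amines) with a
   logged warning. Phenols, anilines, pyridines and amides are left
   neutral by default: their pKas sit on the wrong side of 7.4 for the
   "most prevalent form" reading. This is a documented default, not a
   claim about any particular reference pipeline; the table is data
   and can be edited.

Charge class is read off the ionized form: an anionic atom not
balanced by an adjacent cation marks the molecule acidic, an
unbalanced cation basic, both zwitterionic, neither neutral. The
adjacency test keeps internally charge-separated groups (nitro,
N-oxides) neutral while still counting permanent cations such as
quaternary ammonium as basic. Idempotence and atom-order invariance
are tested on the full fixture library.

## Descriptors

Computed on the pH 7.4 form, except logP which uses the neutral parent
so logP and logD(7.4) stay comparable: MW; Crippen atom-contribution
logP; Lipinski N/O-count HBA and NH/OH-count HBD; rotatable bonds
(strict, amides excluded); SSSR ring count; Ertl fragment TPSA.
Absolute logP/TPSA values can shift versus commercial calculators; the
package's comparisons are distributional, which is what those shifts
leave intact.

**logD(7.4)** is the closed-form correction
`logD = logP − Σ_groups log10(1 + 10^{±(pH − pKa)})` (acids `+`, bases
`−` in the exponent's sign convention) over the ionization rules that
fired, using the rule pKas. It is a transparent, testable surrogate,
not an independent lipophilicity model, and is pluggable. It
guarantees `logD ≤ logP`, with equality exactly for non-ionizable
molecules.

Fingerprints are 2048-bit Morgan, radius 2 (diameter 4).

## Diversity

All-pairs Tanimoto similarity (`|a∧b| / |a∨b|`; defined as 1 for two
empty vectors, which valid molecules never produce) binned at width
0.025 over [0, 1]; the reported peak is the *left edge* of the modal
bin after 3-bin moving-average smoothing, ties resolved by raw count
then lower bin. Subset selection is sphere exclusion (leader): visit
molecules in a seed-shuffled order, retain a molecule iff its
similarity to every retained molecule is strictly below the threshold
(default 0.65). This guarantees (a) no retained pair at/above the
threshold and (b) every excluded molecule within the threshold of a
retained one. The algorithm is order-dependent, hence non-
deterministic across visit orders; the seed makes it reproducible, and
both guarantees are property-tested across seeds. Retained-set sizes
are *not* asserted monotone in the threshold — leader algorithms are
known not to be.

## Profiles

Summaries per set: n, median (midpoint convention for even samples),
mean, sd, histograms (MW 25 Da, logP/logD 0.5, TPSA 10 Å², unit bins
for counts) and range percentages (MW < 500 Da, logP ∈ [0, 5],
TPSA < 120 Å² by default). Missing values are excluded and counted;
percentages are over valid values only. Comparisons are descriptive —
side-by-side medians and overlaid histograms. No significance testing
is attached: the analysis argues by distributional inspection, and the
package deliberately does not go further.

Gram stratification classifies each assay's organism through a shipped
lookup table (exact species first, then genus; unknown names map to
`unclassified`, never an error) and applies the active definition per
Gram class, so a compound can be active in both classes. Temporal
profiles give per-year medians for years with at least 10 (default)
valid compounds. Chemotype subsets match SMARTS cores (β-lactam,
fluoroquinolone, oxazolidinone shipped) and flag subsets under 40
members as too small to compare.

## Synthetic data

The generator defines the package's study conditions. Defaults: 600
compounds (the acceptance run uses 1000); 5 % marketed antibacterials
(MAD) and 15 % other marketed drugs (MOD); of the research remainder
35 % antibacterial-active, 10 % antibacterial-inactive, 5 % with only
slightly-active records; 25 % of antibacterial actives also
biochemically active (BAAA), 30 % of antibacterially untested research
compounds biochemically active (BAAI) and 10 % biochemically inactive;
20 % censored records; 70:30 µg/ml:µM unit mix; 50/40/10
Gram-positive/negative/unclassified organisms; 15 % salt-bearing
records; MW medians 385 Da (research), 420 (MAD), 320 (MOD) with
60 Da spread, years 1975–2015. These are round, field-typical values
chosen once to exercise every pipeline branch with materially sized
strata.

Structures come from an 18-template library spanning the four charge
classes (including penicillin, fluoroquinolone and oxazolidinone cores
so the chemotype matcher has real targets) rather than random graphs:
templates guarantee chemical validity and known charge classes. MW is
tuned by prefixing methylene units toward a per-compound target, so a
designed median is achievable to within the CH₂ lattice (±7 Da).
Labels are constructed decisively — values keep a safety margin from
every cutoff band, so unit round-tripping (which uses the parent MW,
differing by ~1 Da per protonation from the pH 7.4 form) can never
flip a label, and set memberships are recovered *exactly*; statistical
tolerance is confined to property summaries. The recovery test allows
4 asymptotic standard errors of a Normal sample median
(1.2533 σ/√n) plus 10 Da of lattice/ionization slack.

What the generator does **not** emulate: real ChEMBL's property
marginals, assay heterogeneity, activity-type zoo, erroneous entries
and natural-product chemotypes. Passing tests therefore demonstrate
the pipeline's correctness and its ability to recover designed
effects, not any claim about real ChEMBL distributions.

## Pipeline

Stage order: read → standardize → label/matrices → sets →
diversity-reduce → descriptors → profiles → report. Standardization
runs before labelling (earlier than a naive reading of the analysis
flow would suggest) because the µg/ml ↔ µM conversion needs the
desalted parent's molecular weight, and fingerprints should be
computed on canonical parents. One root seed drives the only
stochastic stage (subset selection); reruns are byte-identical. Set
sizes are reported both before and after diversity reduction — which
of the two a reference analysis tabulated is ambiguous, so both are
kept. The temporal profile runs on the full (unreduced) active set,
where per-year counts are meaningful. Failures abort with the stage
name and the counters accumulated so far; exit codes distinguish input
errors (2) from stage failures (3) in the CLI.

## Known limitations

- Rule pKas are per-group constants; no continuous pKa prediction, no
  tautomer enumeration beyond nitro/aromatic normalization, no
  stereochemistry normalization.
- logD(7.4) inherits Crippen logP's biases and the rule table's
  coarseness; absolute logD values should not be compared against
  commercial calculators, only across sets computed the same way.
- The extraction filters that would select assay records from a real
  ChEMBL export (accepted activity types per class) are a configurable
  judgement call; defaults accept MIC/MIC50/MIC90 and
  IC50/Ki/Kd/EC50.
- Gram classification is a name lookup; mixed-organism panels and
  atypical organisms (e.g. *Mycoplasma*, which lacks a cell wall) fall
  to `unclassified` unless the user extends the table.
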