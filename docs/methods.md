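# Methods

## The framework

`rxntree` optimizes molecules by chaining *virtual chemical reactions* instead
of editing molecular graphs freely, so every generated compound arrives with a
synthetic route. Three learned components cooperate:

1. **Template classifier (GCN).** A molecule is encoded as per-bond-type
   adjacency indicators A⁽ᵗ⁾ ∈ {0,1}ⁿˣⁿ (t ∈ {single, double, triple,
   aromatic}) and node features F ∈ ℝⁿˣᵈ. Graph convolution layers compute
   X⁽ˡ⁺¹⁾ = σ(Σₜ Ã⁽ᵗ⁾ X⁽ˡ⁾ Wₜ⁽ˡ⁾) with Ã⁽ᵗ⁾ = Dₜ⁻¹(A⁽ᵗ⁾ + I) (row
   normalization with self-loops, chosen here; only "a normalized adjacency"
   is prescribed by the architecture family). Bias-free per-node dense layers
   and permutation-invariant sum aggregation yield a graph vector that is
   scored against all reaction-template classes. Predicted templates whose
   reactant-side SMARTS has no substructure hit on the molecule are removed
   before any reaction is attempted.

2. **Conditional forward-synthesis transformer.** A standard encoder–decoder
   transformer (sinusoidal positions, post-layer-norm, ReLU feed-forward)
   maps reactant token sequences to product token sequences. The reaction
   template is injected as a single `<t_i>` prefix token on the encoder side
   only. The unconditional twin is identical but sees the bare reactant, so
   it must marginalize over every reaction the corpus admits — the
   conditional/unconditional accuracy gap quantifies how ambiguous forward
   synthesis is without reaction-type information. Beam search uses
   length-normalized (mean) log-probability; hypotheses are validity-filtered
   with RDKit, canonicalized and deduplicated, keeping drop counts.

3. **QSAR reward.** A random-forest classifier over 2048-bit ECFP6
   fingerprints returns the raw probability of the active class, a pure
   function of the canonical SMILES, cached, always in [0, 1]. Per-target
   hyperparameter presets (drd2 / akt1 / cxcr4) ship alongside a small
   default forest for the synthetic task.

**Monte Carlo tree search.** Nodes are molecules; an edge is one virtual
reaction. Each iteration: *selection* descends by maximal UCB score
Q(sᵢ) + 2·C_p·√(ln N(s_p)/N(sᵢ)) with unvisited children scoring +∞ (ties
break on beam-rank then template index); *expansion* conditions a beam search
on each of the top-k filtered templates and adds the decoded products as
children (each node expands once); *simulation* rolls out a fixed schedule —
5 sampled templates × 1 greedy molecule × 2 steps — and values the node by
the maximum reward over the ≤ 25 leaf products (falling back to shallower
products, then the node's own reward, on dead ends); *backpropagation* adds
the value along the path to the root. Defaults: C_p = 1/√2, 200 iterations,
expansion k = 10, max depth 10. Simulation templates are drawn without
replacement from the GCN's filtered, renormalized distribution.
Every distinct molecule seen in expansion or simulation enters the result set
with its reward, depth and replayable route; duplicates reached by different
routes keep the max-reward route.

## The synthetic grammar

Desk-scale training uses a hand-written grammar of 10 aromatic
medicinal-chemistry transforms (bromide amination / methoxylation /
cyanation, acid amidation / esterification, amine acetylation /
sulfonamidation, nitro reduction, O-demethylation, phenol acetylation), each
a reaction SMARTS applied at the match site with the lowest canonical atom
rank, so every (reactant, template) pair has exactly one product. Partner
reagents are implicit in the transform, mirroring single-reactant corpora.
Two transforms (nitro reduction, O-demethylation) are flagged
`single_product`, the annotation used for deprotection-like reactions whose
outcome is unique; during enumeration they contribute only their top beam
product.

Reactants are scaffold × substituent combinations steered so that the mean
number of applicable templates per reactant ("ambiguity") hits a target; the
generator fails loudly if the realized mean misses by more than 25%. At the
default ambiguity 3, a product predictor blind to the template is right at
most once in three — the exact bound is computed by enumerating the dataset
(per reactant, the best achievable hit count is its modal product count).

With `closure_depth > 0` the grammar is rolled forward: reachable products
become reactants of further records, as in a real corpus where one patent's
product is another's starting material.

Activity labels are a hidden pharmacophore rule (default: N-alkylsulfonamide,
`[NX3][SX4](=O)(=O)[CX4]`) XOR-ed with Bernoulli label noise. The
pharmacophore is reachable from an aryl bromide in two steps (amination, then
sulfonamidation), which gives the search a provably attainable optimum.

What the grammar does *not* emulate: reagents/solvent noise, multi-product
reactions, yields, stereochemistry, atom-mapping errors, and the sheer
template diversity (10 vs 1000 classes) of patent-scale data. Passing tests
therefore demonstrate the machinery — conditioning, filtering, search,
metrics — not chemical coverage.

## Study conditions

Two fixed setups drive the tests and `scripts/acceptance.py`:

* **Conditioning experiment.** 120 reactants at ambiguity 3 (~360 records,
  no closure), record-level 80/10/10 split. The conditional model is scored
  by held-out perfect accuracy (greedy decode, canonicalized, per molecule);
  measured ≥ 0.9. The unconditional twin is scored dataset-wide against the
  enumerated Bayes bound (~1/3): on held-out records of a *seen* reactant the
  attainable accuracy is ~0 by construction (the held-out record is exactly
  the product the trained model did not commit to), and on held-out
  *reactants* it measures generalization, not the ambiguity bound — so the
  bound comparison is only meaningful over the full enumerated set. Measured
  ≈ 0.31 vs bound 0.333.

* **Search study.** 30 starting reactants rolled to full closure
  (~230 records over ~130 reactants). The search transformer is trained
  without dropout until it reproduces the whole corpus (perfect accuracy
  ~1.0): its job in the search is to *be* the reaction model, so every
  (molecule, template) pair the search can encounter is in-distribution at
  every depth. Searches run 50 iterations; effectiveness uses beam width 5,
  the bookkeeping (conservation / determinism / oracle route replay) check
  uses width 1 — at width > 1 the expansion deliberately admits rank-2+
  beam hypotheses, which on a *deterministic* grammar are model guesses that
  cannot coincide with the single oracle product.

## Numerical and design choices

* **Tensor plumbing.** Both networks run on a small in-repo reverse-mode
  autodiff over numpy (`rxntree.nn`): broadcasted arithmetic, batched matmul,
  rectifier, softmax, layer norm, embedding, dropout, padded cross-entropy,
  Adam. Gradients are verified against central finite differences to 1e-6.
* **Toy transformer size.** d_model 64, 2+2 layers, 4 heads, FFN 128,
  batch 64, Adam 1e-3 halved every 80 epochs, early stopping on validation
  perfect accuracy with best-epoch weight restore. This is the smallest
  configuration that reliably converges on the grammar; the full-scale
  preset (512, 6+6, 8 heads, FFN 2048, dropout 0.1, batch 128) is retained.
* **Decoding.** Max decode length = 1.5 × longest training target + 8.
  Beam ties break by stable sort order, making decoding deterministic for a
  fixed checkpoint.
* **Tokenization.** Molecular-transformer-style regex segmentation: bracket
  atoms, two-letter halogens and %nn ring closures are single tokens;
  detokenization is exact.
* **Pairing.** Multi-molecule reactions reduce to the (reactant, product)
  pair with maximal ECFP4/2048 Tanimoto similarity; ties break
  lexicographically on canonical SMILES so the result is order-independent.
  One RDKit canonicalization procedure is used package-wide.
* **GCN defaults.** Hidden 256, 1 convolution layer, 3 dense layers,
  learning rate 4e-4 (the full-scale best values); the toy preset shrinks to
  hidden 64 / lr 2e-3. Node features: one-hot element (C,N,O,S,F,Cl,Br,I,
  other), one-hot degree 0–5, formal charge, aromatic flag, ring flag
  (d = 18).
* **Diversity.** IntDiv_p(G) = 1 − (|G|⁻² Σ T(m₁,m₂)ᵖ)^{1/p} over ordered
  pairs including self-pairs, ECFP4/2048; reports use p = 1.
* **Threshold metric.** "Reward > 0.5" is a strict inequality; the
  percentage uses the set's total as denominator.
* **Starting-material filter.** Removes molecules with a ring of more than 8
  atoms, molecular weight ≥ 300 (boundary removed), and those containing
  none of: halogen, carbonyl, non-aromatic double/triple bond, or a
  nucleophilic substituent (–OH, –SH, –NH₂/–NH–). Aromatic bonds do not
  count as unsaturation, so benzene alone does not qualify.
* **Ligand efficiency.** |docking score| / heavy atoms, hydrogens excluded.
* **Class imbalance.** The reward forest uses no imbalance correction; the
  held-out split is stratified 90/10 by class.

## Problem sizes

Desk-scale sizes were chosen so the full suite trains three neural models and
runs all searches on a single CPU: conditioning corpus ~360 records,
search corpus ~230 records, transformer ~260k parameters, searches of
50 iterations. Search-time beam results and reward values are cached by
canonical SMILES (both are pure functions of the checkpoint), which makes
repeated and multi-seed searches cheap.

## Known limitations

* The unconditional twin's accuracy is only interpretable against the Bayes
  bound dataset-wide (above); a reactant-grouped split measures systematic
  generalization instead, where this small model reaches ~0.5 conditional.
* The grammar's determinism makes "one product per (reactant, template)"
  exact; real corpora violate this, so corpus-perfect training accuracy is a
  toy-scale property only.
* Template classes here are separable from functional groups; the reported
  GCN accuracies say nothing about 1000-class patent-scale performance.
* FCD and synthetic-accessibility scoring are intentionally out of scope;
  external tools can consume the generated CSV.
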