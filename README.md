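# etanet

Structure-based protein function annotation from local evolutionary
similarity: pick small templates of evolutionarily important surface
residues, match them geometrically between protein structures, transfer
EC-number annotations by reciprocal-match voting, and diffuse labels
globally over the weighted match network.

## Who this is for

Structural bioinformaticians who want to annotate enzyme function for
structures without close homologs. Sequence similarity fails in that regime,
but catalytic machinery — a handful of residues in a specific 3D
arrangement — is often conserved across folds. This package implements the
full template-match-and-vote pipeline plus its network-diffusion extension,
end to end on self-contained synthetic benchmarks (no downloads, no external
services).

## The method

1. **Template selection.** Per-residue evolutionary-importance ranks (lower =
   more important; consumed as input) are swept by coverage; the first
   single-linkage spatial cluster to collect ≥ 11 important surface residues
   (accessible area > 2 Å²) nominates the functional site. A 5- or 6-residue
   template is grown greedily from it: best-ranked residue nearest the
   cluster center first, then best-ranked remaining members nearest the
   evolving midpoint. *Multiple-template* modes (M5R/M6R) add one template
   per additional non-overlapping cluster holding better-ranked surface
   residues.
2. **Paired-distance matching (PDM).** A template is placed residue by
   residue onto type-compatible target residues so that every pairwise
   Cα–Cα distance agrees within 2.5 Å; each complete match gets a
   superposition RMSD.
3. **Filtering.** Self-matches and matches with RMSD > 2 Å are removed; an
   SVM over `[rmsd, |Δpercentile-rank|₁..₆]` (a virtual sixth residue — the
   mean of five — maps 5-residue matches onto the same contract) keeps only
   matches that are both geometrically and evolutionarily similar. Matches
   must be significant in *both* directions (reciprocity) to count.
4. **Voting.** Each unique reciprocal partner contributes one vote per EC
   number it carries; the plurality wins, ties abstain. An iterative mode
   (ALL) runs 6R → 5R → M6R → M5R and takes the first answer.
5. **Network diffusion.** Every reciprocal match is an edge weighted by
   `W = exp(-s)` with `s = ½[(rmsd−μ)/σ + (ETScore−μ)/σ]`. For each function,
   labels `y ∈ {+1, −1, 0}` diffuse by solving `(I + αL) f = y` (graph
   Laplacian `L = D − W`); scores standardized over unknown nodes give a
   confidence z per prediction, and the argmax-z function is the call.

## Worked example

```bash
python examples/02_function_prediction.py
```

prints, for a 20-protein benchmark with two planted sites per protein and a
scrambled primary site in 25% of them:

```
  6R: accuracy=1.00 sensitivity=0.75 f_measure=0.94 (15 TP / 0 FP / 5 no prediction)
 M6R: accuracy=1.00 sensitivity=1.00 f_measure=1.00 (20 TP / 0 FP / 0 no prediction)
 ALL: accuracy=1.00 sensitivity=1.00
```

The single-template mode abstains on the five proteins whose primary site
was scrambled (its template finds no reciprocal partner); the
multiple-template mode recovers all of them through the secondary-site
template at unchanged accuracy — the sensitivity gain that motivates
multiple templates. `examples/01_template_matching.py` shows template
selection and paired-distance search on one protein pair, and
`examples/03_network_diffusion.py` shows label diffusion breaking 4–4 voting
ties with z-score confidences.

A thin CLI wraps the same functions:

```bash
eta generate --out bench/ --seed 7
eta predict --data bench/ --mode M6R
eta diffuse --data bench/ --alpha 1.0 --unknown-fraction 0.25
```

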