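# cksaap-ubsite

Prediction of protein **ubiquitination sites** — the lysine (K) residues to
which ubiquitin is covalently attached — directly from sequence, for people
studying the ubiquitin–proteasome system and other K-modification biology
(primarily in yeast, where the sequence context around modified lysines is
best characterized).

## The method

Every lysine in a query protein is represented by the sequence window of
2n + 1 = 27 residues centered on it (truncated at protein termini).  The
window is encoded as the **composition of k-spaced amino-acid pairs
(CKSAAP)**: for each spacing k = 0..5, the count of every ordered residue
pair at positions (i, i + k + 1) is divided by N_total = L − k − 1, the
number of such pairs the fragment holds (26 at k = 0 for a full window).
Concatenating the six 400-dimensional composition blocks gives a
2400-dimensional feature vector that captures short-range residue
collocations — the signature of the short linear motifs enriched around
ubiquitination sites — rather than strict position-specific conservation.
A one-hot "binary" encoding over the padded 21-letter alphabet
`ACDEFGHIKLMNPQRSTVWYO` (21 × 26 = 546 dimensions) is included as the
baseline it outperforms.

Classification uses a C-SVC with RBF kernel
K(u, v) = exp(−γ‖u − v‖²), C = 2.0 and γ = 8.0 by default (the optimum of a
512-point grid search over C ∈ [0.5, 8.0], γ ∈ [0.5, 16.0], step 0.5).
Because candidate negatives vastly outnumber known positives, the final
predictor is an **ensemble of 10 SVMs**, each trained on all positives plus
a different seeded random negative subset of equal size; the prediction
score is the mean of the members' decision values.  Operating thresholds
are calibrated empirically at 2% and 10% false-positive rate on reference
negatives.

Evaluation follows the same design: balanced 1:1 sets, 100-fold stratified
cross-validation, pooled out-of-fold scores for one ROC/AUC, single-point
Ac/Sn/Sp/MCC at decision threshold 0, all repeated over 10 negative
resamplings and reported as mean ± SD.  Chi-squared and information-gain
rankings of the 2400 features identify the residue pairs (e.g. `ExE`, `EQ`,
`KxxK`) that drive the classification.

## Worked example

Simulate a labeled site table with three implanted pair signals, train the
10-member ensemble, and score every lysine in a query protein:

```sh
cksaap-ubsite simulate --npos 300 --nneg 1200 \
    --implant ExE:0.8 --implant EQ:0.8 --implant KxxK:0.8 \
    --seed 4 --out sites.tsv
cksaap-ubsite train --sites sites.tsv --members 10 --seed 4 --out model.ub
# train logs: C=2.0 gamma=8.0 thresholds={"0.02": 0.238094, "0.1": -0.046874}
printf '>YDR099W\nMSTEEQAKLEEEQLKAEEDKIAEELKKSEETPEQQELARQESLKEEAKSM\n' > query.fa
cksaap-ubsite predict --model model.ub --fasta query.fa --fpr 0.10 --out predictions.tsv
```

`predictions.tsv` holds one row per lysine with the averaged ensemble score
and the call at the 10%-FPR threshold (−0.046874 for this model):

```
protein_id	position	score	call
YDR099W	8	0.040790	yes
YDR099W	15	0.111566	yes
YDR099W	20	0.116450	yes
YDR099W	26	0.256577	yes
YDR099W	27	0.248030	yes
YDR099W	44	0.080260	yes
YDR099W	48	-0.069939	no
```

Lysines embedded in the E/Q-rich context score well above the cutoff; the
C-terminal K48 in a blander context does not.  Ranking the features
recovers the implanted pairs at the top:

```sh
cksaap-ubsite rank --sites sites.tsv --method chi --top 5 --out ranking.tsv
```
```
rank	feature	score
1	ExE	680.907
2	EQ	650.449
3	KxxK	554.959
4	KE	142.551
5	KxxxxE	140.225
```

`cksaap-ubsite evaluate --sites sites.tsv --repeats 10 --folds 100 --seed 1
--out report/` writes the per-repeat Ac/Sn/Sp/MCC/AUC table, their
mean ± SD summary, ROC points and per-position residue enrichment calls.

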