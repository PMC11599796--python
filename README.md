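# domsuite

Multi-assay dominance analysis for laboratory mice.

Social rank in group-housed mice is usually inferred from repeated dyadic
contests — homecage fights and chases, territorial urine marking, the tube
test, and competition for a cued reward — but different assays can disagree,
and in some strains one assay can rank animals *opposite* to the others.
`domsuite` is a tested toolkit for quantifying exactly this: it scores
dyadic contest streams into dominance ratings, classifies per-pair
hierarchy stability, discovers behavioral states from two-animal pose
tracking during reward competitions, and compares dominance measures across
assays. A synthetic-data module generates match streams from a known latent
hierarchy and arena pose recordings with scripted behavioral states, so
every stage of the pipeline is validated against planted ground truth.

It is aimed at behavioral neuroscientists and computational ethologists
working with cage-level dominance data (4 mice per cage is the default
throughout) and SLEAP-style keypoint tracking.

## Models and statistics

**Elo rating with ties.** Matches are consumed in chronological order. With
ratings $R_A, R_B$, the expected win probability for A is

$$E_A = \frac{1}{1 + 10^{(R_B - R_A)/400}},\qquad R'_A = R_A + K\,(S_A - E_A),$$

with $S_A = 1$ (win), $0$ (loss) or $0.5$ (tie), $K = 20$, and every animal
starting at 1,000. Updates are exactly zero-sum, and a cage that never
fights keeps everyone at baseline — which is why this rating is usable for
assays with many ties.

**David's score.** From the win matrix $\alpha$ ($\alpha_{ij}$ = wins of
$i$ over $j$), dyadic proportions $P_{ij} = \alpha_{ij}/(\alpha_{ij} +
\alpha_{ji})$ give

$$DS_i = w_i + w^{(2)}_i - l_i - l^{(2)}_i,\quad
w_i = \sum_j P_{ij},\; w^{(2)}_i = \sum_j P_{ij} w_j,\;
l_i = \sum_j P_{ji},\; l^{(2)}_i = \sum_j P_{ji}\, l_j.$$

Scores sum to zero over a fully interacting group; ties are excluded from
$\alpha$.

**Directional consistency index.** With $H$ the number of decisive
interactions in each dyad's more frequent direction and $L$ the complement,
$DCI = (H - L)/(H + L) \in [0, 1]$: 1 for fully unidirectional cages, 0 for
fully bidirectional ones.

**Outcome and stability rules.** Urine matches are ties when spot counts
differ by fewer than 5 spots or by less than 20% of the larger count.
Reward-competition matches go to the animal winning >50% of decisive
trials. A dyad's hierarchy is *stable* when the same animal wins ≥75% of
tube matches, ≥75% of ≥3 agonistic interactions, ≥60% of decisive
reward-competition trials, or all (non-tied) urine trials; dyads that
cannot be assessed are *unmeasurable*, never silently dropped.

**Pose features and behavioral states.** Two-animal, six-node tracks
(nose, forehead, ears, thorax, tail base) are gap-interpolated and
Savitzky–Golay-smoothed (window 25 frames). Seven per-frame features —
summed and |difference| of thorax speeds, of port–nose distances, and of
port–thorax–nose orientation angles (folded to [0°, 180°] for rotation
invariance), plus the thorax–thorax distance — are invariant to which
animal is labeled first. Every third frame is kept, features are z-scored
over the pooled recordings, and k-means (default k = 8, seeded) partitions
frames into behavioral states; UMAP is available for plotting only. The
over-representation of a rank-difference stratum $i$ in cluster $j$ is

$$\mathrm{enrichment}(i,j) = \frac{n_{ij}}{n_{i\cdot}} - \frac{n_{\cdot j}}{N},$$

whose rows sum to zero.

## Worked example

The `analysis/` scripts run the whole pipeline on synthetic cohorts.
Step 01 simulates two 8-cage cohorts; in the second ("cd1") the tube test
is inverted against the latent hierarchy. Step 05 then prints, for that
cohort, the Elo cross-assay correlation matrix:

```
$ python analysis/01_simulate_cohorts.py ... python analysis/05_compare_assays.py
== cd1 ==
Elo correlation matrix across assays:
           agonistic  reward   tube  urine
agonistic      1.000   0.969 -0.980  0.956
reward         0.969   1.000 -0.951  0.943
tube          -0.980  -0.951  1.000 -0.960
urine          0.956   0.943 -0.960  1.000
reversal fraction in tube-involving stable pairs: 0.99
```

The tube row is uniformly negative and almost every dyad that is stable in
both the tube test and another assay has *opposite* dominant animals — the
pipeline recovers the planted inversion. For the straight cohort all
off-diagonal correlations are ≥ 0.88 and the reversal fraction is 0.01.

Step 04 clusters pose features from recordings in which
rank-difference-3 dyads dwell 1.6× longer in the
"one at the port, one nearby facing away" state:

```
cluster 2 matches the near-avert script; its rank-difference-3 enrichment = +0.072
```

i.e., frames from maximally rank-separated pairs are over-represented in
the cluster that k-means matched to that scripted state.

A single-command variant of the same flow is available via the CLI:
`domsuite run --config run.yaml` (see `domsuite --help` for the
stage-by-stage subcommands).

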