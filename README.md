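# bbumfit

False-discovery-rate correction for **directional** differential-expression
experiments, using the bi-beta-uniform mixture (BBUM) model of p-value
distributions.

## The problem

Some perturbations can move their *direct* targets in only one direction.
Knocking out a factor that degrades microRNAs (e.g. the ZSWIM8 ubiquitin
ligase, which mediates target-directed miRNA degradation) can only *raise*
the abundance of its direct substrates; transfecting a miRNA can only
*lower* its direct targets.  Yet a standard DE analysis of such experiments
also reports many significant changes in both directions caused by
*secondary* effects — downstream consequences of the perturbation that are
roughly symmetric between up- and downregulation.  A plain
Benjamini–Hochberg (BH) cutoff therefore mixes primary and secondary
effects, while ad hoc fixes (lowering the cutoff until the "wrong"
direction is empty) give erratic, dataset-dependent stringency.

## The model

The raw p values of the experiment are modelled as a three-component
mixture.  In the **signal** direction (where primary effects can occur):

    X ~ θ·Beta(ar, 1) + (1−θ)(1−λ)·Beta(a, 1) + (1−θ)λ·U(0, 1)

with density

    f(p) = θ·ar·p^(ar−1) + (1−θ)(1−λ)·a·p^(a−1) + (1−θ)λ .

`Beta(ar, 1)` (steep, since r < 1) carries primary effects, `Beta(a, 1)`
carries secondary effects, and the uniform carries nulls.  The
**background** direction is fit simultaneously to the same model with
θ = 0, r = 1 — no primary component — so the background half anchors the
secondary-effect shape.  One shared parameter set (λ, a, θ, r) is estimated
by maximum likelihood (BFGS in logit-bounded coordinates, six fixed starts,
θ bounded to (0, 1−2α)).

Each signal-direction feature then receives a BBUM-FDR-adjusted p value

    p_BBUM = 1 − θ·p^(ar) / F(p) ,

the expected FDR among features at or below its raw p — the directional
analogue of a BH-adjusted p value — and is called significant at
`p_BBUM < α`.

Extreme background outliers (features knocked down by an orthogonal
mechanism) can distort the fit.  The default *modified* procedure first
fits with r allowed up to 10; a fitted r ≥ 1 signals such contamination,
and the smallest background p values are trimmed one at a time (at most
min(5 %, 10) points) until r < 1.

## Worked example

```python
import numpy as np
from bbumfit import BBUMParams, BBUMCorrector, bbum_sample

# a synthetic experiment: 800 features per direction, 15% primary signal
truth = BBUMParams(lambda_=0.5, a=0.3, theta=0.15, r=0.1)
p_sig, labels = bbum_sample(800, truth, seed=1)
p_bg, _ = bbum_sample(800, truth, seed=2, background_only=True)
p = np.concatenate([p_sig, p_bg])
is_signal = np.arange(1600) < 800

corr = BBUMCorrector(alpha=0.05).fit(p, is_signal)
print("fitted:", corr.params_)
calls = corr.significant(p_sig)
tp = np.sum(calls & (labels == "primary"))
print(f"{calls.sum()} calls, {tp} true primaries, "
      f"FDR {(calls.sum()-tp)/max(calls.sum(),1):.3f}")
```

Output:

```
fitted: BBUMParams(lambda_=0.5377..., a=0.2734..., theta=0.1377..., r=0.1067...)
72 calls, 71 true primaries, FDR 0.014
```

The fit recovers the generating parameters (truth: λ = 0.5, a = 0.3,
θ = 0.15, r = 0.1), and the realised false-discovery proportion among the
72 calls stays below the intended 5 % for this dataset.

The same workflow runs on a DESeq2-style results table from the command
line:

```sh
bbumfit correct results.tsv --out annotated.tsv --signal-direction up
bbumfit benchmark --out bench.tsv --n-sims 200 --outliers
```

`correct` annotates every feature with `p_bbum` and a category
(`both_significant`, `bbum_only`, `padj_only`, `outlier_trimmed`,
`not_significant`); `fit` and `simulate` expose the fitting and the
labelled-dataset generator.

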