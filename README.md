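# valimpute

Estimating the predictive performance of a clinical prediction model is
delicate when the development data contain missing values. Evaluating a
model on the data used to fit it overstates performance (optimism), so
internal validation — bootstrap, subsampling or cross-validation — is
required; and missing covariate values call for multiple imputation
(MI). The two can be combined in different orders, and the order
matters: imputing the full data first lets future test observations see
the training observations through the imputation models.

`valimpute` is a Python library for biostatisticians and epidemiologists
developing binary-outcome (logistic) prediction models on incomplete
data. It implements and compares three combination strategies:

* **Val-MI** — draw validation splits first, then impute the training
  and test parts separately (outcome included);
* **MI-Val** — impute the full data first (outcome included), then
  resample the completed copies;
* **MI(-y)-Val** — as MI-Val, but the outcome is withheld from the
  imputation models.

## The estimators

For a performance measure θ (AUC, Brier score, calibration
intercept/slope, and the added-performance measures ΔAUC, categorical
and continuous NRI, IDI), with θ̂^{Orig,Orig} the apparent value,
θ̂^{OOB} the mean fit-on-resample / evaluate-on-test value, and
θ̂^{BS,BS}, θ̂^{BS,Orig} the resample-apparent and resample-on-original
averages, the package reports

    θ̂^{opt.corr.} = θ̂^{Orig,Orig} − (θ̂^{BS,BS} − θ̂^{BS,Orig})
    θ̂^{0.632}    = 0.368 θ̂^{Orig,Orig} + 0.632 θ̂^{OOB}
    θ̂^{0.632+}   = (1 − w) θ̂^{Orig,Orig} + w θ̂^{OOB},
                    w = 0.632 / (1 − 0.368 R),
                    R = (θ̂^{OOB} − θ̂^{Orig,Orig}) / (θ̂^{noinfo} − θ̂^{Orig,Orig})

with averages pooled across all B×M resample×imputation sets and the
no-information value θ̂^{noinfo} equal to 0.5 for the AUC, 0 for added
measures, and a permutation average for the Brier score. Confidence
intervals centre the bootstrap percentile spread of the apparent values
at the 0.632+ estimate; an analytic DeLong interval (Rubin-pooled over
imputations) is provided for apparent (Δ)AUC.

A simulation engine generates data with a prescribed theoretical
(added) AUC — solving the class-mean shift Δμ from
AUC = Φ(½√(Δμᵀ Σ⁻¹ Δμ)) — and imposes MCAR, MAR or blockwise-MAR
missingness with exact per-covariate missingness fractions, so every
strategy can be evaluated against an independent-test-set truth.
Imputation is MICE with predictive mean matching (5 donors, type-1
matching, normality-improving transformations chosen by Shapiro–Wilk).

## Worked example

`examples/estimate_performance.py` simulates an incomplete data set
(n=200, p=10 covariates, theoretical AUC 0.66, 25 % MAR missingness)
and runs Val-MI with B=100 bootstrap draws and M=1 imputation:

```
  apparent: 0.7803
       oob: 0.6636
  opt_corr: 0.6854
     e0632: 0.7066
 e0632plus: 0.6932
  R = 0.416, w = 0.746
95% CI for the 0.632+ AUC: (0.5875, 0.7164)
```

The apparent AUC (0.780) is optimistic; the out-of-bag value (0.664) is
pessimistic; the 0.632+ estimate (0.693) weighs them by the relative
overfitting rate R and sits close to this configuration's
independent-test truth (≈0.69, see `examples/compare_strategies.py`,
which also shows the characteristic optimism of MI-Val and pessimism of
MI(-y)-Val). The interval is the modified percentile CI.

The other example scripts cover data simulation
(`simulate_incomplete_data.py`), imputation and Rubin pooling
(`impute_with_pmm.py`), and performance of a fixed model on incomplete
future data (`future_missingness.py`). A thin CLI wraps the same
functionality:

```sh
valimpute simulate --config sim.yaml --out data/ --replicates 10 --seed 1
valimpute validate --in data/sim_1.csv --strategy val-mi -B 100 -M 1 \
    --measure auc --ci jiang --seed 2 --out report.json
```

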