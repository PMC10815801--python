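# aptapanel

In-silico analytics for Cell-SELEX aptamer discovery and diagnostic
evaluation.

Aptamers are short single-stranded oligonucleotides (here, 76-nt ssDNA with
a 30-nt random region) selected by iterative rounds of Cell-SELEX to bind
tumor cells specifically. Turning a selection experiment into a validated
diagnostic panel involves a chain of computational steps, and this package
implements that chain as a tested, reusable library with a thin CLI:

* **SELEX enrichment** (`aptapanel.selex`) — per-round FASTQ processing:
  sliding-window Phred quality trimming (default window 4, mean-quality
  threshold 20), a minimum-length filter (default 74 nt), exact-sequence
  frequency counting across rounds, and nomination of the top-k most
  abundant final-round sequences as candidate aptamers.
* **Binding affinity** (`aptapanel.binding`) — nonlinear least-squares fit
  of the total binding model

  `response(X) = Bmax·X/(X + Kd) + NS·X + Background`

  to flow-cytometry dose–response data (X in nM), statsmodels-style:
  `SaturationBindingModel(data).fit()` returns estimates, asymptotic
  standard errors, diagnostics and a `summary()`.
* **Panel diagnostics** (`aptapanel.diagnostics`) — sensitivity
  `TP/(TP+FN)`, specificity `TN/(FP+TN)` and accuracy `(TP+TN)/N` of
  individual aptamers and of panels (union rule: a sample is recognized if
  any member stains it at or above the positivity threshold) on labelled
  tissue cohorts, with stratified recognition tables by class, molecular
  subtype, stage, grade or TNM.
* **Target shortlist** (`aptapanel.shortlist`) — the proteomic filter
  cascade nominating candidate aptamer targets: ≥2-fold tumor/control
  abundance increase, membrane evidence plus plasma-membrane localization,
  and a per-cell-line expression phenotype matching the panel's recognition
  pattern.
* **Trajectory analysis** (`aptapanel.trajectory`) — Kabsch superposition
  RMSD, GROMOS conformational clustering (greedy neighbor counting at an
  RMSD cutoff, default 2.5 Å) with representative structures, and
  hydrogen-bond occupancy with a ≥20 % reporting rule.
* **Synthetic data** (`aptapanel.simulate`) — seeded generators for every
  input above with planted ground truth, so the whole chain is testable
  end to end without external data.

## Worked example

Fit a simulated five-dose titration (25–400 nM, three replicates, additive
noise) and evaluate the bundled tissue-microarray recognition table:

```python
from aptapanel import simulate as sim, fit_kd, datasets
from aptapanel.binding import BindingModelParams
from aptapanel.diagnostics import evaluate_panels

table = sim.gen_binding_curve(sim.BindingSimConfig(
    true_params=BindingModelParams(Bmax=100, Kd=139, NS=0.02, Background=5),
    noise_sd=3.0, seed=7))
print(fit_kd(table).summary())

cohort = datasets.load_tma_cohort()
print(evaluate_panels(cohort, [[a] for a in datasets.APTAMERS])
      [["panel", "TP", "FP", "FN", "TN",
        "sensitivity_pct", "specificity_pct", "accuracy_pct"]]
      .to_string(index=False))
```

```
Saturation binding fit (Bmax*X/(X+Kd) + NS*X + Background)
  n obs: 24   RSS: 313.819   converged: True   evals: 8
  Bmax              104.3 +/- 36         units
  Kd                132.9 +/- 56         nM
  NS             0.006919 +/- 0.0505     units/nM
  Background        4.033 +/- 1.3        units

 panel  TP  FP  FN  TN  sensitivity_pct  specificity_pct  accuracy_pct
AptaB1  12   1  78   9               13               90            21
AptaB2  23   1  67   9               26               90            32
AptaB3   9   1  81   9               10               90            18
AptaB4  40   4  50   6               44               60            46
AptaB5  47   3  43   7               52               70            54
```

The fit recovers the planted Kd (139 nM) within its reported uncertainty —
the wide Kd standard error reflects the genuine identifiability limits of a
four-parameter fit on five doses. The diagnostic table is recomputed from
the bundled recognition marginals (10 adjacent tissues, 50 primary
carcinomas, 40 lymph-node metastases; tumor classes pooled, positivity =
any staining): the individually weak but complementary aptamers motivate
panel combinations, which `evaluate_panels`/`exhaustive_panels` score under
the union rule.

The same operations are available from the shell, e.g.

```
aptapanel sim selex --seed 1 --out sim/
aptapanel selex --rounds R8=sim/R8.fastq ... --min-len 74 --top-k 5 --out out/
aptapanel kd --data binding.csv --out fit.csv
aptapanel diagnose --cohort cohort.csv --panels "AptaB4+AptaB5" --out diag/
aptapanel shortlist --proteome proteome.csv --recognized MDA-MB-468,BT-474,MCF-7 \
    --unrecognized HCC-1937 --out cascade/
aptapanel traj cluster --frames trajectory.pdb --cutoff 2.5 --out clusters.csv
```

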