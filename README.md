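# vegindex

Phenology-aware vegetation-type mapping from multi-temporal multispectral
imagery: modified red-edge vegetation indices, standard-deviation-sum
screening of feature band combinations, a hierarchical knowledge decision
tree, a random-forest comparator, and confusion-matrix accuracy assessment —
with a synthetic-scene generator so the whole workflow runs end to end
without any imagery.

## The problem

Nature-reserve vegetation maps need per-pixel class labels for types that
look almost identical to the classical vegetation indices.  In the Lingkong
Mountain reserve system that this toolkit models, seven types matter: crops,
scrub grass, *Pinus tabuliformis*, *Quercus wutaishanica*, pine-oak mixed
forest, *Larix principis-rupprechtii*, and shaw (a local broadleaf thicket).
Five of these share nearly the same red/NIR reflectance in every season, so
NDVI-style indices cannot separate them — but their *seasonal trajectories*
in the red-edge and SWIR bands differ.  The method here amplifies those
differences with indices whose two operands may come from different
acquisition dates.

## The method

With surface reflectance ρ in [0, 1] on ten Sentinel-2-style bands
(Blue, Green, Red, RE1–RE3, NIR, RE4, SWIR-1, SWIR-2) over six dates
(Feb, Apr, Jun, Aug, Oct, Dec):

**Typical indices** (per date):
RVI = RED/NIR, DVI = NIR − RED, NDVI = (NIR − RED)/(NIR + RED).
(The RVI orientation is the one used by the source method; the conventional
NIR/RED form is available via a flag.)

**Modified indices**, each developed for one class by screening candidate
(band, date) operand pairs and keeping the pair with the smallest sum of
within-class standard deviations:

| Index | Formula | Isolates |
|---|---|---|
| UTM-DMI  | RE4(Feb) − SWIR1(Feb) | pine-oak mixed forest (≈ 0; others < 0) |
| MTM-NDQI | (1 − RE4(Jun) − RE4(Oct)) / (RE4(Jun) + RE4(Oct)) | *Quercus* (low side) |
| MTM-DSI  | RE2(Jun) − RE2(Aug) | scrub grass (negative side) |
| MTM-RSI  | (RE2(Jun) − RE2(Oct)) / RE2(Oct) | shaw (high side) vs *Larix* |

The **optimal feature set** is {NDVI(Dec), NDVI(Apr), UTM-DMI, MTM-NDQI,
MTM-DSI, MTM-RSI}.  A **knowledge decision tree** applies one threshold rule
per feature in that order, peeling off one class at a time; pixels surviving
all rules are *Larix*.  Thresholds are calibrated from training plots as the
minimal-misclassification 1-D split (expert overrides supported).  A
250-tree random forest (√p features per split) serves as the comparator on
any feature set.  Accuracy uses the pixel confusion matrix (rows =
classified, columns = ground truth): OA = trace/N, PA_i = N_ii/N_+i,
UA_i = N_ii/N_i+, and Kappa = (N·trace − Σ N_i+N_+i)/(N² − Σ N_i+N_+i).

## Worked example

```sh
python examples/03_knowledge_tree.py
```

trains the hierarchy on 60% of the plots of a simulated scene and prints the
calibrated rules and the verification report:

```
calibrated rules (applied in order; leftover pixels -> larix):
  NDVI@DEC  >=   0.4543  -> pinus
  NDVI@APR  <=   0.3198  -> crops
  UTM-DMI   >=  -0.0279  -> pine_oak
  MTM-NDQI  <=   0.3854  -> quercus
  MTM-DSI   <=  -0.0183  -> scrub_grass
  MTM-RSI   >=   0.1740  -> shaw
...
OA: 100.00%  Kappa: 1.00
```

Each rule fires on the side of the threshold where its class's training mean
lies; at the default noise level the six gaps are wide enough that the
held-out 252 verification pixels classify perfectly.  The other examples
cover scene simulation and index maps (`01`), screening (`02`), the
random-forest feature-set comparison (`04`, where the optimal set beats the
time-series NDVI/RVI/DVI sets by 12–30 OA points on synthetic scenes), and
the published-matrix accuracy report (`05`, OA 95.56%, Kappa 0.95).

A thin CLI mirrors the stages:
`vegindex simulate|indices|screen|train-tree|classify|evaluate|pipeline`
plus `train-rf`/`classify-rf`; runs write a manifest with per-output
checksums, and identical config + seed reproduces outputs bit-for-bit.

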