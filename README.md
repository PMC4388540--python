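# petquant

Dynamic-PET quantification with an **image-derived arterial input function
(IDAIF)**: two-tissue-compartment kinetics, Logan graphical analysis
(arterial-input and reference-region forms), arterial-ROI partial-volume
modelling, and V_T-constrained kinetic fitting — as a tested library and CLI,
exercised end-to-end on synthetic dynamic-PET data.

## What it does

Given a dynamic PET acquisition (or pre-extracted regional time-activity
curves), a vessel mask or angiography-like volume, and region masks:

1. **`arterial_roi`** — threshold-segments the vessels, smooths the mask to
   scanner resolution (8 mm FWHM Gaussian), automatically thresholds to a
   16 cc arterial ROI inside a user-supplied box and a 100 cc outer volume
   whose difference is the background shell, extracts TACs, and computes the
   partial-volume **recovery coefficient** r.
2. **`idaif`** — reconstructs the plasma input from a large tissue curve by
   inverting a pair of one-tissue models (early washout k2, late effective
   washout k2a, linearly blended between the tissue peak and 40 min),
   converts plasma to whole blood with a population parent-fraction model,
   and fits (K1, k2, k2a, s) so that r·C_B + s·C_BG matches the measured
   arterial-ROI curve in least squares.
3. **`logan`** — graphical analysis: slope = V_T with arterial input, slope =
   DVR with a reference region (default window 30–60 min, k2′ = 0.16/min),
   plus the mean cortical DVR summary.
4. **`kinetic_fit`** — full two-tissue fit per region with V_T fixed at the
   Logan value, estimating (K1, K1/k2, k3) directly; DVR_kinetic =
   V_T/(K1/k2). A nested F-test collapses spurious k3 to the one-tissue
   model.
5. **`synthetic_data`** — seeded generators for everything above: bolus
   input, per-region 1TC/2TC curves on the 26-frame 60-min schedule
   (12×10 s, 3×1 min, 11×5 min), the mixed arterial-ROI curve, and a
   curved-tube vessel phantom. Every bundle carries its generating truth for
   recovery tests.

Times are minutes throughout; activity units are arbitrary but must be
consistent. Input TACs are assumed decay-corrected.

## CLI

```sh
# generate a synthetic subject (optionally with the vessel phantom volumes)
petquant simulate --seed 1 --cohort pib_pos --with-phantom --out work/sub

# vessel segmentation -> ROIa / BG masks + recovery coefficient
petquant roi --mra work/sub/mra.nii.gz --box 28:70,32:64,36:60 --out work/roi

# fit the arterial input function from the TAC table
petquant idaif --tacs work/sub/tacs.csv --r 0.25 --out work/fit

# regional V_T / DVR_REF / DVR_kinetic table
petquant quantify --tacs work/sub/tacs.csv --aif work/fit/aif.csv \
    --ref cerebellum --out work/table.csv
```

Configuration is a single YAML file (see `petquant/config.py` for defaults)
passed with `--config`; CLI flags override it. TAC CSVs have columns
`frame_start_min`, `frame_duration_min`, then one column per region; the
column names `plasma`, `whole_blood`, `arterial_roi`, `background` carry
their role.

## Library example

```python
import petquant as pq

bundle = pq.make_subject("pib_pos", seed=1)
params, cp, diag = pq.fit_idaif(
    bundle.tacs["cerebellum"], bundle.croia, bundle.cbg,
    r=bundle.truth["r"], pf=bundle.truth["parent_fraction"],
)
table = pq.quantify_subject(bundle.tacs, cp, ref_region="cerebellum")
print(table[["region", "V_T", "DVR_REF", "DVR_kinetic"]])
```
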