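# Methods

`seaweed_cdr` quantifies the net climatic effect of basin-scale floating
seaweed ("ocean afforestation"), using the 2018 Great Atlantic Sargassum
Belt (GASB) as the natural analogue: a bloom that built up 18.8 Mt of wet
biomass between November 2017 and June 2018 over up to 6093 km² of the
(sub)tropical North Atlantic. This note describes the models, their
assumptions, the parameters that matter, and the numerical choices.

## Seawater carbonate kernel

The CO2 system is solved from total alkalinity (TA) and dissolved inorganic
carbon (DIC). The alkalinity balance includes carbonate, borate, water,
phosphate, silicate, free hydrogen, bisulfate and fluoride terms; pH (total
scale) is found by safeguarded bisection on [2, 12] to 1e-9 in pH, fully
vectorised so gridded fields solve in single array passes. The constant set
is pinned to the conventional open-ocean recommendation: Lueker et
al. (2000) carbonic acid on the total scale, Dickson (1990b) boric acid,
Dickson (1990a) bisulfate, Perez & Fraga (1987) fluoride, Millero (1995)
water/phosphoric/silicic acid (seawater-scale, converted to total), Weiss
(1974) CO2 solubility, Uppström (1974) boron-to-salinity. A frozen table of
the constants at S=35, T=25 °C ships as
`seaweed_cdr/data/equilibrium_constants_reference.csv`; the test suite pins
the live code to it and to the original publications' check values
(pK1 = 5.8472, pK2 = 8.9660, K0 = 0.02839 mol kg⁻¹ atm⁻¹, pKB = 8.5975).
pCO2 is reported as CO2*/K0 (the fugacity correction, ~0.3%, is neglected;
the timescale and feedback ratios are insensitive to it). Only surface
pressure is supported; MgCO3 chemistry, other pH scales and isotopes are
out of scope.

Derived quantities, all by central finite differences with a step of
1 µmol/kg and a halved-step convergence check in the tests:

* **psi** — mol CO2 evaded per mol CaCO3 precipitated. Precipitation
  removes 1 mol DIC and 2 mol TA per mol CaCO3; after the parcel
  re-equilibrates with an unchanged atmosphere the evaded CO2 is
  `psi = 2·(∂DIC/∂TA)|pCO2 − 1`. At TA = 2350 µmol/kg, DIC = 2047.5
  µmol/kg, S = 35, T = 25 °C this gives 0.630. psi grows with pCO2 (0.57 at
  300 µatm to 0.70 at 600 µatm — the well-known calcification positive
  feedback) and *falls* slightly with temperature at fixed TA/DIC (0.632 at
  20 °C to 0.628 at 30 °C): warm water partitions more of an alkalinity
  change into carbonate ion, so less of the perturbation appears as CO2.
* **Revelle factor** `B = (∂pCO2/pCO2)/(∂DIC/DIC)` at constant TA (≈9.7 at
  the reference state), increasing as DIC approaches TA.
* **R = [CO2*]/DIC** (≈0.0057), the sliver of the DIC pool in direct
  contact with gas exchange.
* **Gas exchange**: Schmidt number from the Wanninkhof (2014) quartic in
  temperature (valid −2 to 40 °C; 668 at 20 °C), transfer velocity
  `G = 0.251·U10²·(Sc/660)^−1/2` cm/h, divided by 360,000 to m/s.

## Carbon partition and the CDR budget

Wet weight converts to total particulate carbon (TPC) at 0.0543 g C per g
wet weight. Epibiont calcifiers (bryozoans, spirorbid polychaetes — the
seaweed itself does not calcify) contribute CaCO3 equal to 9.4% of wet
weight on annual average (single-sample range 4.3–21.4%); dividing by
100 g/mol gives PIC, the remainder of TPC is POC. At the central values the
PIC:POC ratio is 0.262 (the source biomass study reports 0.265 from its own
monthly TPC values; the ~1% difference is inherited from their input data,
not a model choice) and the endpoints are 0.105 and 0.899, matching the
reported 0.11–0.9.

The theoretical CDR of a bloom is the four-term budget

    CDR = POC_seaweed − psi·PIC_seaweed − POC_plankton + psi·PIC_plankton

with every term in Mt C. The PIC terms are **CO2-equivalents** (psi-weighted
carbonate), not raw carbonate masses: this is what makes the published
term value 0.13 Mt C consistent with the 0.21 Mt C of seaweed PIC at
psi = 0.63, and what the published 100-mol bound arithmetic does. The
plankton terms come from nutrient reallocation: N (0.002 g/g), P
(0.0002 g/g) and Fe (1.009e-5 g/g) bound in the seaweed are unavailable to
phytoplankton, whose foregone fixation is nutrient × C:X (C:N 8 under
N-limitation, the regional default; C:P 170 under P-limitation) and whose
foregone calcification is that POC × 0.01 (planktonic PIC:POC), credited
back psi-weighted. Fe is computed and reported but never treated as
limiting. Discounts may exceed 100% and are never clipped — the worst-case
budget is genuinely net-negative. Carbon is 12.011 g/mol throughout.

Bound propagation works on a 100-mol-TPC basis: the lower bound pairs the
21.4% CaCO3 fraction with the low seaweed C:N of 16, the upper bound 4.3%
with C:N 108; nets are scaled to Mt C by the bloom's TPC. The continuous
evaluation gives −3.3 and +77.8 mol per 100 mol TPC (the printed "−3" and
"77" round intermediates to whole mols; the lower bound is a small
difference of ~50-mol terms, so intermediate rounding shifts it visibly).

DOC production multiplies each month's standing wet weight by the incubation
release rate of 288 µg C g⁻¹ d⁻¹ and the true calendar length of the
labelled month. Mt C converts to Gt CO2 via 44.009/12.011 ÷ 1000.

## Equilibration timescales

A mixed-layer DIC deficit decays by air-sea exchange at rate G·B·R/h, so

    tau_CO2 = h / (G · B · R) = h·DIC / (G · B · [CO2*])

in seconds, reported in months of 365/12 days. (Quoting the timescale with
R in the numerator, as is sometimes done, only works if "R" denotes the
DIC-to-CO2 ratio; with R = [CO2*]/DIC it must divide.) tau increases with
h and decreases with wind, B and R; temperature moves it far less than
depth or wind, as the scenario sweep shows.

Scalar sweeps derive DIC from (TA = 2350 µmol/kg, equilibrated pCO2 =
410 µatm) by a dedicated bracketing inversion (tolerance well below
0.01 µmol/kg). The gridded path averages monthly components (h, R, G, B)
over the selected season *first* and computes tau from the averages — a
regression test pins this order, which differs from averaging monthly taus.
Cells with any missing input stay masked. Region statistics are unweighted
by default with an optional cosine-latitude weighting; tau_res is strictly
an input field (no circulation modelling).

## Albedo forcing

Rafts raise surface albedo by Δa (0.01–0.07 measured over seagrass
canopies; surface rafts plausibly at or above the top of that range, so
scenarios span 0.01–0.1). The daily reduction in absorbed shortwave is
`Qs↓·Δa·(1−α_atm)` with α_atm = 0.2 absorbed by the atmosphere and Qs↓ in
J m⁻² d⁻¹ (W/m² × 86,400). Monthly totals (× calendar days × covered area)
accumulate to PJ/y. The CDR counterpart is the logarithmic CO2 forcing,
5.35 W/m² per e-fold, over the 510e12 m² Earth surface, with 2.124e9 t C
per ppmv: −98.8 GJ per tonne C per year at 410 ppm (computed with `log1p`;
forming ln((C+5e-10)/C) directly loses four digits). Crossover divides the
albedo total by the per-cycle CDR forcing, assuming instantaneous air-sea
transfer, a fixed atmosphere, and a constant albedo footprint — all
deliberately generous to the albedo side. Reductions carry a negative sign;
crossover uses magnitudes.

## Logistics

Shipping: bulk carriers emit 2.7–33.9 g CO2 per tonne-km (large to small
vessels); one tonne wet weight holds 54,300 g C ≈ 199 kg CO2, giving
0.0014–0.017% per km. BECCS capture efficiency 0.8–0.9 leaves a 10–20%
loss. Harvest, drying and loading are excluded — the numbers are lower
bounds, and no full life-cycle assessment is attempted.

## Synthetic inputs

The generator exists so the full pipeline runs without any data download.
It reproduces *anchors and ranges*, not real covariance or satellite noise:

* **Bloom series** — 14 months (Nov 2017–Dec 2018), cosine-ramp rise from
  0 to exactly 18.8 Mt in June 2018, cosine decline to an end value scaled
  by the coverage ratio (807/6093 of the peak, ≈2.5 Mt — the series' only
  invented value, chosen so biomass and coverage decline proportionally);
  coverage runs 870 → 6093 → 807 km². Deterministic regardless of seed.
* **Gridded fields** — twelve 2018 months on a 1° grid over 5°S–25°N,
  89°W–15°E; each field is a seeded sum of low-order spatial harmonics with
  a mild seasonal modulation, mapped strictly inside its subtropical range
  (TA 2250–2450 µmol/kg, pCO2 380–440 µatm, T 20–30 °C, S 34–37, MLD
  10–110 m, U10 4–10 m/s, tau_res 0.2–2 months). An optional mask knocks a
  rectangular data hole into TA/pCO2, mimicking climatology gaps in
  marginal seas.
* **Solar flux** — a low-latitude seasonal cosine within 180–280 W/m² plus
  small seeded jitter.

Consequently the gridded tau map and the yearly albedo totals test
*structure* (monotonicity, masking, linearity, order of magnitude — the
synthetic map spans ~4–16 months, squarely in the reported 2.5–15 month
range), not the published map or the 181–1811 PJ/y endpoints, which depend
on the real climatologies and supplementary monthly tables; the biomass
CSV override hook (`seaweed-cdr synth --override-biomass`) ingests the real
series when available. The same applies to the ~1 Mt C DOC total, which the
synthetic series reproduces at order one.

## Problem sizes and determinism

Everything is desk-scale: scalar solves take ~3 ms, the 1°
(31×105×12-month) tau map under two seconds, and the full test suite a few
seconds. Tests use a 5° grid where the full resolution adds nothing. All
randomness flows through a single integer seed per generator call; repeated
runs are bit-identical.

## Known limitations

* No reference carbonate program is bundled; correctness rests on published
  check values, conservation/round-trip invariants and the reproduced
  anchor values rather than a second software implementation.
* The carbonate solver is surface-only and total-scale-only.
* tau_res, mixed-layer depth and all climatological fields are inputs;
  nothing is derived from profiles or circulation.
* DOC fate, external-nutrient scenarios, seafloor re-exposure, bioaerosol
  albedo feedbacks and full logistics life cycles are out of scope, as is
  any satellite detection modelling.
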