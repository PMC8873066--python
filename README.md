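# tablesim

Similarity metric and clinic-attribution analysis for surgical
instrument-table setups.

A table setup is the arrangement of instruments on a 1920 × 1080 pixel
simulated table surface: each placed instrument has an identity, an x/y
position in pixels and an orientation angle in degrees.  The package
provides:

* **`tablesim.metric`** — the pairwise table similarity score `s_tab`:
  per instrument, the weighted sum of Euclidean position distance and
  minimal angular difference (`w_trans·d_trans + w_rot·d_rot`) when the
  instrument is on both tables, or a fixed penalty `w_miss` when it is
  on only one; the sum is normalized by the size of the matching
  universe.  0 means identical setups; larger means less similar.
  Duplicate instances of one instrument are paired by minimum-cost
  assignment.  Default weights: `(w_trans, w_rot, w_miss) = (1, 1, 1000)`.
* **`tablesim.analysis`** — leave-one-out clinic attribution: each setup
  in turn is held out, its mean score against every clinic's remaining
  setups is computed, and the clinic with the lowest mean is the
  predicted affiliation.  Also: total (all-others) means, the most
  representative setup, and report rendering.
* **`tablesim.questionnaire`** — aggregation of closed yes/no
  questionnaire responses (yes-counts per clinic) into per-clinic and
  participant-weighted total percentages, with support for chained
  conditional questions.  `tablesim.studydata` bundles the yes-counts of
  the three-clinic study (5 participants each).
* **`tablesim.synthetic`** — a generator of synthetic multi-clinic
  collections: per-clinic archetype layouts perturbed by Gaussian
  positional jitter, wrapped-Gaussian angular jitter, instrument dropout
  and extra instruments — for end-to-end testing and for characterizing
  classification accuracy versus noise level.
* **`tablesim.io_setups`** — readers/writers for an XML dialect
  (`<setups><setup id clinic><instrument id label x y angle/>`), with a
  configurable element/attribute name mapping for externally produced
  files, and an equivalent flat CSV format.

## CLI

```sh
# pairwise score with per-instrument breakdown
tablesim compare --input setups.xml acqua4 insel1

# full pairwise matrix as CSV
tablesim matrix --input setups.xml --out matrix.csv

# leave-one-out clinic attribution; writes table1.csv/.txt, matrix.csv
tablesim loocv --input setups.xml --w-trans 1 --w-rot 1 --w-miss 1000 --out report/

# questionnaire aggregation (bundled study data by default)
tablesim questionnaire
tablesim questionnaire --counts counts.csv --specs questions.csv --out report/

# synthetic multi-clinic collection
tablesim simulate --clinics 3 --nurses 5 --instruments 20 \
    --sigma-xy 15 --sigma-angle 10 --p-drop 0.05 --seed 42 --out synth.xml
```

Exit codes: 0 success, 1 validation error, 2 I/O error.

## Conventions

Coordinates: origin at the top-left of the surface, x rightward,
y downward, pixels; placements outside the 1920 × 1080 surface are
rejected.  Angles: degrees, normalized to `[0, 360)`; only angle
differences enter the metric, via the minimal rotation in `[0, 180]`.
The normalization denominator of the score sum is injectable
(`union` [default] | `max-size` | `matched-only`), as is the
total-average strategy in the analysis (`count-weighted` [default] |
`clinic-mean`).
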