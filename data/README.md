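# Reference benchmark data

The 96-well reference benchmark (wells A01–H12: sigmoidal curves, hook
effect-bearing curves of varying severity, no-plateau curves and negative
reactions, with per-well human hook ratings) is published alongside the
PCRedux R package as `inst/hookreg.rdml` and is **not redistributed here**.

To run the reference-plate acceptance test, place in this directory:

- `hookreg_plate.csv` — the 96 amplification curves as a wide CSV
  (first column `cyc`, one fluorescence column per well, header row with
  well ids). `hookdetect analyze` can read the original RDML directly;
  converting to CSV keeps this directory text-only:

  ```python
  from hookdetect.io import read_rdml, write_csv_plate
  write_csv_plate(read_rdml("hookreg.rdml"), "data/hookreg_plate.csv")
  ```

- `hookreg_labels.csv` — the human ratings, two columns `well_id,label`
  with label `y` (hook) or `n`.

Without these files the test `test_reference_plate_confusion_counts`
fails with a message pointing here; every other test is self-contained
(fixtures are generated at run time by `hookdetect.synth`).
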