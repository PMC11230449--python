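# blindcut

Blinded analysis of video and image data, headless and scriptable.

In studies that score videos or still images by eye — multi-well-plate
behavioral assays, microscopy fields, wildlife imagery — the scorer's prior
knowledge of which specimen got which treatment is a real source of bias.
`blindcut` removes that knowledge from the scoring step while keeping a
single researcher in charge of the whole study:

1. **Segment** — cut each video or image into labeled rectangular regions
   (e.g. one per well, labels `A1`…`E12`); segments from several files of
   one media type can be pooled into one analysis.
2. **Randomize** — shuffle the pooled segments with a Fisher–Yates shuffle
   driven by a recorded seed (PCG64, identity pinned in the session file),
   and assign each presentation position an opaque blind ID (`S001`, …).
3. **Annotate** — score segments one at a time against blind IDs only; the
   session persists atomically after every note, so analysis can be halted
   and resumed without disturbing the original random order.
4. **Unblind & export** — re-join every note to its label and source file
   and write a results table (CSV or XLSX).

The core correctness claim is the round-trip theorem: for any manifest,
seed and note assignment applied through the blinded interface, unblinding
recovers exactly the intended label → note mapping. Equivalently, with
`π` the seeded permutation taking presentation position `k` to segment
index `π(k)`, annotation stores notes under position `k` and export applies
`π` to re-attach them — the export is the exact inverse of the blinding.

Supported media: `.png`, `.jpg/.jpeg`, `.bmp` images and `.avi` video
(raw 24-bit frames or MJPEG, both read and written with a built-in RIFF
container layer). `.mp4` files can be probed for dimensions, frame count
and frame rate from their container metadata, but their compressed streams
cannot be decoded here. Image crops are pixel-exact and PNG round trips
are bit-exact; resolution is never resampled.

A fixtures module generates synthetic well-plate images and videos with
per-well ground truth (condition tag, motion amplitude, trajectory seed),
so the entire workflow is testable with no external data.

## Worked example

Simulate a 60-well plate (rows A–E of a 96-well plate), segment it on the
well grid, randomize, annotate by script, and export:

```sh
blindcut simulate --out sim --kind image --rows 5 --cols 12 --seed 1
blindcut segment sim/plate.png --grid 5x12 --origin 16,16 --pitch 32 \
         --stages latency --out run
blindcut randomize run/manifest.json --seed 7
blindcut status run/session.json
```

prints

```
segments: 60
annotated: 0
pending: 60
status: in_progress
```

`blindcut annotate run/session.json` then presents each blinded segment
file in randomized order and prompts for a note per stage; a scripted run
(`--script notes.json`, mapping blind IDs to notes — here each note is the
blinded segment's mean pixel intensity) reports `60/60 annotated
(complete)`. Finally

```sh
blindcut export run/session.json --out results.csv
```

writes a table with one row per annotated segment, ordered by label; its
first lines are

```
label,source_file,blind_position,latency
A1,plate.png,47,120.6
A2,plate.png,14,120.1
A3,plate.png,52,120.1
```

`blind_position` is the rank at which that segment appeared during blinded
scoring. The same flow is available as a library; see the docstrings in
`blindcut.segmentation`, `blindcut.session` and `blindcut.export`.

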