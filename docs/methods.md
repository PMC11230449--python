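# Methods

## The blinding model

`blindcut` treats observer blinding as an invertible bookkeeping problem.
An analysis is a manifest: a set of media sources of one kind (all video or
all image), an ordered list of labeled rectangular segments pooled across
those sources, and an ordered list of user-named analysis stages. Blinding
is a seeded permutation `π` of the segment indices plus an opaque renaming:
presentation position `k` shows segment `π(k)` under the positional blind
ID `S(k+1)` (zero-padded to at least three digits). Annotation attaches one
free-text note per stage to a blind ID; unblinding applies `π` to re-attach
each note to its label and source file. Because `π` and the ID assignment
are recorded in the session file, the export step is the exact inverse of
the blinding step — the round-trip property the test suite checks
exhaustively over randomized manifests, seeds and note assignments.

What the annotator can observe is deliberately minimal: a blind ID and the
path of a blind-named copy of the segment file. Segment files produced at
extraction are named by definition index (`seg_0007.png`), which already
carries no label; session creation additionally copies them into a
`blinded/` folder under their blind-position names, so even a user browsing
the results folder mid-analysis sees nothing ordered by, or named after,
the labels. The label ↔ blind-ID key lives in a separate key file written
next to the session file, consumed by the export step. Logs never pair a
label with a blind ID.

## Randomization

The shuffle is an explicit Fisher–Yates pass driven by NumPy's PCG64
generator, recorded in every session file as `pcg64-fisher-yates-v1`. The
pinning matters: a session must reproduce its permutation on any machine
and any interpreter release, which rules out "whatever the standard
library's shuffle does this version". PCG64's bit stream is covered by
NumPy's random-stream compatibility policy, and the Fisher–Yates loop here
is part of this package, so the pair is stable. When no seed is supplied
one is drawn from system entropy (below 2^31) and recorded, so every
session remains reconstructible from its manifest and seed alone.

Uniformity is verified empirically: over 10,000 seeds at n=4, each of the
24 permutations occurs within the 99% binomial band around 1/24.

## Session persistence

Sessions are JSON with a schema version. Saves are atomic (write to a
temporary file, then rename), and an annotation recorded on a session that
knows its save path is persisted before the call returns, so a crash
between annotations loses at most the note being typed. Loading validates
the permutation (each index exactly once), blind-ID uniqueness, stage
coverage of every annotation, and the PRNG identity; violations raise a
corrupt-session error rather than silently continuing with a broken order.
Re-annotation requires an explicit overwrite flag.

## Media layer

The internal pixel model is 8-bit RGB; grayscale and palette images are
promoted and alpha is dropped on read. One model keeps crop-correctness
reasoning trivial. Crops are pure subarray views — never resampled — so a
segment has exactly the source's resolution, and image segments round-trip
bit-exactly through PNG.

Video I/O is a self-contained RIFF/AVI container layer with two codecs:
raw 24-bit DIB frames (lossless, the default — chosen so the pixel-exactness
guarantees extend to video frames in tests) and MJPEG via Pillow's JPEG
codec (lossy, much smaller, quality 92). Video segment files are
re-encoded rather than stream-copied; cropped video cannot generally be
bit-exact anyway, and the manifest always retains the rectangle
coordinates, so any segment can be re-rendered from the source. MP4 files
are probed through an ISO base-media box parser (dimensions from `tkhd`,
frame count from `stsz`, frame rate from `mdhd`), but no H.264/H.265
decoder is provided, so frame access on MP4 raises a codec error instead
of guessing. A file whose header contradicts its extension is reported as
corrupt rather than silently re-interpreted.

## Segmentation conventions

Rectangles are 0-based and half-open, stored as `(x, y, width, height)` in
the plain-text definition file and converted internally; this removes
off-by-one ambiguity at the cost of one convention to document. Labels
follow the well-plate scheme — row letter A–Z, column 1–36 — parsed
case-insensitively and canonicalized to upper case; duplicates anywhere in
a manifest raise immediately, and segments are never renamed. Rectangles
hanging over the frame edge are clamped, as an interactive drag would be;
rectangles entirely outside the frame are rejected. Overlapping segments
are allowed with a logged warning, since generously drawn adjacent wells
may overlap. Mixed image+video manifests are rejected up front.

## Synthetic fixtures

The generators emulate the scene the tool targets: a top-down view of a
well plate, one specimen per well. Each well is a bright disk (intensity
200 on background 40) holding one dark particle of radius 2 px; in videos
the particle performs a Gaussian random walk with per-well step scale
("motion amplitude", px/frame), reflected at the well wall. Per-well
trajectory seeds are spawned from one master seed via a `SeedSequence`, so
wells are decorrelated yet the whole plate is reproducible; ground truth
(label, condition, amplitude, seed) is stored beside, never inside, the
media, so no label is burned into pixels and blinding tests are
meaningful.

The default layout is the 60-animal design the workflow is demonstrated
on: rows A–E of a 96-well plate, four condition blocks of three columns
(15 wells each) — a convulsant dose series at amplitudes 8, 4 and 2
px/frame plus an untreated control at 0.5 px/frame. The amplitudes are not
a kinematic model of seizure behavior; they encode the one feature the
workflow tests need, "distinguishable activity levels per condition", with
the control kept slightly above zero because live untreated animals still
move. Consequences for interpretation: passing tests show the *workflow*
(segmentation, blinding, resume, unblinding, export) is correct on media
with condition-dependent content; they say nothing about scoring real
animal behavior, lighting, occlusion, or camera noise, none of which the
fixtures model.

The measurement oracle is motion energy: the mean absolute inter-frame
difference, averaged over every pixel channel and over frame transitions.
It is exactly 0 for a static clip; a single pixel changing by 10 between
the two frames of an H×W clip scores 10/(H·W).

## Problem sizes and numerical choices

The end-to-end check runs 100 replicates of a 5×12-well plate video at 20
frames, 10 fps, 32 px well pitch (416×192 px frames) — small enough to
render, segment and score a replicate in a fraction of a second while
keeping 60 wells and four conditions per replicate; per-condition mean
motion energy must rank in the injected amplitude order in at least 95 of
100 replicates. The round-trip theorem is checked on 200
(manifest, seed) sessions across four grid shapes, with notes derived from
segment-file digests and compared against a label → digest map computed by
an independent route (direct array slicing plus Pillow encoding). Shuffle
uniformity uses 10,000 seeds at n=4 against 99% binomial bounds
(z = 2.576). Frame rates are stored in the AVI header as a rational with
fixed denominator 1000, so any fps that is a multiple of 0.001 round-trips
exactly.

## Known limitations

- No MP4/H.264 decoding; MP4 is probe-only. Analyses of MP4 recordings
  must transcode to AVI first (raw or MJPEG).
- Raw AVI is large (width × height × 3 bytes per frame); MJPEG is the
  practical codec for long recordings, at the cost of lossy segments.
- Single annotator per session; no concurrent writers, no inter-rater
  statistics.
- Rectangular regions only, by design: free-form outlines would reintroduce
  selection bias.
- The column cap of 36 cannot label a 1536-well plate's 48 columns; the
  scheme is kept as specified.
- Downstream statistics on the exported table (dose-response ANOVA etc.)
  are out of scope; the export is designed to feed standard tools.
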