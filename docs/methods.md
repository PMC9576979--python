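# Methods

## What the package models

`poctbridge` implements the connectivity chain between a point-of-care blood
analyzer and a research database, plus the accounting that quantifies what
that chain replaces.  Three layers:

1. **A conversation protocol** (`messages`, `conversation`): a
   POCT1-A-style, device-initiated push of cartridge results over
   XML-over-TCP, with per-message acknowledgment.  Both roles are pure state
   machines — `(state, event) -> (new state, actions)` with the clock passed
   in — so every protocol rule is testable without sockets; thin runners
   interpret the action lists over a transport.
2. **A device emulation** (`simulator`, `panels`): a synthetic i-STAT-style
   analyzer with a FIFO unsent-record queue, "Successful/Failed Transmit" UI
   notifications, and scripted faults (dropped links, never docked, absent
   manager).
3. **A transcription-error study** (`transcription`): a stochastic model of
   technicians hand-copying printed results, a value-level mismatch
   classifier, and the arithmetic of error rates, capture gain and
   personnel time.

## Delivery semantics

The core guarantee is exactly-once persistence under an at-least-once
transport:

* The device removes a record from its queue only on an `AA` acknowledgment
  referencing that record's message (no-loss).
* The manager sends `AA` only after the sink reports a durable write
  (transactionality); a persist failure is answered `AE` immediately so the
  device notifies the user rather than waiting out a timeout.  Silence is
  reserved for genuine transport loss and has the same effect through the
  acknowledgment timeout (default 10 s, configurable).
* `result_id` (serial + timestamp + sequence) is the idempotency key; sinks
  drop rows whose id is already stored, turning retransmission into
  exactly-once storage.  The file sink reloads its id set on restart, so the
  property survives process restarts.

Together these give the tested invariant: records dequeued = records
persisted = `AA` acks, under any scripted failure plan with eventual
success.

Design choices that were genuinely open:

* **Push model.** The device volunteers observations after its status
  message; the manager never requests a topic.  A manager-initiated
  request/response would also be protocol-legal, but the push model matches
  the dock-and-transmit workflow the stack exists for and keeps the message
  set to six types.
* **Failure fan-out.** Sink failure maps to `AE` (fail fast, user notified
  this session) rather than withheld acknowledgment; `AR` is reserved for
  out-of-order messages, which do not change the receiver's phase.
* **Session granularity.** One TCP connection is one session; a reconnect
  restarts at Hello.  Retransmission therefore happens across sessions, not
  within one, which is simpler to reason about and matches how a docked
  analyzer actually behaves.
* **Device end-states.** `DRAINED` means every record was acknowledged;
  `TERMINATED` means the session ended early with records retained.  The
  retained in-flight record returns to the *front* of the queue (FIFO,
  oldest first).

## Panels and the synthetic analyzer

The CG4 blood-gas panel carries 13 values of which 8 are the ones a
technician would copy from the printed strip: temperature-corrected pH,
pCO2 and pO2, lactate, bicarbonate, base excess, oxygen saturation and
TCO2.  The five machine-only values are the sample temperature, the
*measured* (37 °C) pH/pCO2/pO2, and barometric pressure.  Published
descriptions of this workflow name only seven hand-recorded analytes while
counting eight; the panel here is configuration (YAML/JSON), not a hard-coded
claim, and TCO2 fills the eighth slot.  The CHEM8 electrolyte panel carries
11 values (Na, K, Cl, iCa, TCO2, glucose, BUN, creatinine, Hct, Hgb, anion
gap), all hand-recorded.

The generator draws each analyte uniformly within a swine-plausible sampling
range (shock-model critical care: e.g. lactate 0.3–15 mmol/L, pH 6.80–7.60)
and renders it at the device's display precision.  Measured blood-gas values
are derived from the corrected draw by a uniform perturbation of 1 to
`max_pair_delta_quanta` display quanta (pH up to ±0.06, pCO2 up to
±4.0 mmHg, pO2 up to ±20 mmHg), never zero — so a corrected/measured pair
always differs at display precision and a swap is always detectable.

Study defaults are one experiment day: **16 CG4 + 10 CHEM8 cartridges**,
interleaved chronologically 5–15 min apart.  Everything is deterministic
under a seed, end to end: a fixed (seed, failure plan) reproduces the sink
files byte for byte.

What the generator does *not* emulate: physiologic time-trends within an
animal, inter-analyte correlation (a real acidotic sample has coherent pH,
bicarbonate and base excess), out-of-range flags, cartridge QC failures, and
vendor-exact XML element names (the vendor dialect is not public; this
package fixes its own documented dialect).  Passing tests therefore
demonstrate protocol and persistence correctness, not physiologic realism —
which is the intended scope.

## Transcription-error model

Hand entry is modeled per cartridge entry and per value:

* With technician-specific probability `p_swap`, the whole corrected
  blood-gas triplet is transcribed as the measured triplet (this is a
  per-cartridge event because the technician misreads the strip section,
  not one number).  Two technicians with different habits alternate
  entries; the default pair (0.45 / 0.07, mean 0.26) produces a swap-value
  incidence near one value in ten of all hand-entered CG4 values, the
  regime reported for this workflow, while preserving the observed
  technician asymmetry.
* Each recorded value then independently suffers a single-digit slip with
  `p_typo` (default 0.003 ≈ a few per 1280 values) or an omission with
  `p_omit` (default 0), mutually exclusively.
* The typo generator perturbs exactly one digit by ±1 and never produces
  the value's corrected/measured counterpart, keeping the four classes
  (MATCH, SWAP, TYPO, OMIT) disjoint and the classifier exact.

Classification precedence: absent → OMIT; equal to corrected → MATCH; equal
to the paired measured value → SWAP; anything else → TYPO.  A typo on top of
a swapped value classifies as TYPO — the comparator sees only strings, as a
human QC pass would.

**Rates and rounding.** The denominator of an error rate is individual
values (so 160 CG4 cartridges = 1280 values).  All printed figures use
decimal half-up rounding: rates to 2 decimals, minutes and capture gain to
1.  This reproduces exactly the canonical worked numbers: 238 values per
16+10 study; 127/1280 → 9.92 %; 1/96 → 1.04 %; 120 min over 238 values →
4.0 min per CG4 and 5.5 min per CHEM8; 5 machine-only of 13 values → 38.5 %
capture gain; 25 animals × 2 h → 50 person-hours.

**Parameter recovery.** The validation harness simulates replicate studies
and re-estimates the configured probabilities from classified output: swap
incidence per cartridge (the unit the swap fires on — within-cartridge
values are correlated, so using values as trials would understate the SE),
typo incidence per value, each with a binomial standard error over pooled
trials.  Recovery tests assert agreement within 3 SE at 160 cartridges ×
20 replicates.

## Numerical and operational choices

* Values travel and persist as decimal strings; nothing is ever parsed into
  floats before storage, so stored rows are byte-identical to what the
  device transmitted.  Floats appear only in the analysis layer, after
  `decimal`-based rounding.
* Stream framing is incremental byte-level depth tracking (quotes, comments,
  CDATA and processing instructions handled), emitting each document as its
  root element closes; output is invariant under arbitrary re-chunking of
  the byte stream.  Maximum document size 1 MiB.
* Timestamps are ISO-8601 at seconds precision, UTC, offset-free.
* Defaults: listen on 0.0.0.0:8080; acknowledgment timeout 10 s (tests and
  the acceptance script use 1–2 s to keep fault paths fast); HTTP sink
  timeout 10 s; 2xx → OK, 5xx/transport → retryable, other 4xx → permanent.
* Degenerate inputs: zero-cartridge time apportionment and zero-value rate
  denominators raise rather than return 0; an empty queue yields an
  immediate end-of-topic; an empty delivery batch is OK without a write.

## Problem sizes

The test suite and the reproduction script run one 26-cartridge study for
delivery checks, a 27-session retransmission convergence, and 20 replicates
of 160 CG4 cartridges (25 600 values) for recovery — a few seconds in
total.  These sizes were chosen as the smallest that exercise every queue
state and give recovery SEs well below the asserted 3-SE bands.

## Known limitations

* Single serialized device session at a time; no TLS on the device link
  (transport security is the sink's concern, as in the deployed setting).
* The HTTP sink's dedupe set is per-process; exactly-once across restarts
  is guaranteed only by the file sink (a server-side unique key would do it
  for HTTP).
* The error model treats values as independent given the swap event; real
  technicians make context-correlated mistakes (fatigue, handwriting).
* Vendor-exact i-STAT XML is not reproduced — interoperating with real
  hardware would require mapping this dialect onto the vendor's element
  names behind the same parser interface.
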