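# poctbridge

An open, testable connectivity stack for point-of-care testing (POCT)
devices in research settings — the software half of a "logger box" that sits
between an i-STAT-style blood analyzer and a research database, plus the
analysis that quantifies what it replaces.

Research labs that run bench-top or large-animal critical-care studies use
clinical analyzers (arterial blood gas, electrolytes) heavily, but the
commercial data-management layers that move results into a database are
proprietary and priced for hospital throughput.  The common fallback —
printing each cartridge result and typing it into a web form — costs
technician hours and introduces transcription errors, the dominant one being
copying the *measured* (37 °C) blood-gas value instead of the
temperature-corrected one.  `poctbridge` provides:

* **`messages`** — a POCT1-A-style XML message dialect (six message types,
  per-sender control ids, per-message acknowledgment) with incremental,
  chunking-invariant stream framing.  See `docs/protocol.md`.
* **`conversation`** — pure state machines for both roles (data manager and
  device) plus TCP session runners.  A record leaves the device's unsent
  queue only after an accept-acknowledgment that is itself only sent after a
  durable write: at-least-once retransmission plus an idempotency key gives
  **exactly-once** storage.
* **`simulator`** — a synthetic analyzer: physiologically plausible CG4
  (blood gas, 13 values) and CHEM8 (electrolytes, 11 values) cartridge
  results, a FIFO unsent queue, "Successful/Failed Transmit" notifications,
  scripted faults.
* **`sink`** — database-shaped flattening (one metadata table plus one
  analyte table per cartridge type) delivered to append-only JSONL/CSV files
  or a token-authenticated REDCap-style HTTP endpoint.
* **`transcription`** — the manual-entry error study: a stochastic
  hand-entry simulator (swap / typo / omission, two alternating
  technicians), an exact mismatch classifier, and the accounting arithmetic
  (error rates, per-cartridge entry time, capture gain, person-hours).

## The accounting in one place

For a study of $n_{CG4}$ blood-gas and $n_{Chem8}$ electrolyte cartridges
with $v_{CG4}=8$ and $v_{Chem8}=11$ hand-entered values each:

* values per study $N = n_{CG4} v_{CG4} + n_{Chem8} v_{Chem8}$
  (16 and 10 give $N = 238$);
* entry time per cartridge at uniform per-value cost $t = T/N$:
  $(v_{CG4} t,\; v_{Chem8} t)$ — 120 min gives 4.0 and 5.5 min;
* transcription error rate $= 100\,e/N$ (half-up, 2 decimals):
  127 errors in 1280 CG4 values → 9.92 %, 1 in 96 CHEM8 values → 1.04 %;
* capture gain $= 100\,m/(h+m)$ for $h$ hand-recorded and $m$ machine-only
  values per result: 8 and 5 give 38.5 %;
* person-hours $=$ animals × hours per study: 25 × 2 = 50.

## Worked example

Run the device simulator against the listener (two shells):

```sh
poctbridge listen --port 8080 --sink-dir rows/ --sessions 1
poctbridge --seed 1 simulate --port 8080        # 16 CG4 + 10 CHEM8
```

The listener prints `session 1: persisted=26 acked=26 errors=0`; `rows/`
then holds 26 metadata rows and 26 analyte rows (16 in `cg4.jsonl`, 10 in
`chem8.jsonl`), and the simulator exits with `final queue depth: 0` after
26 "Successful Transmit" notifications.  Kill the listener mid-study and the
remaining records stay queued; the next session delivers them without
creating duplicates.

Simulate the pre-automation workflow — two technicians hand-copying one
study — and its accounting:

```sh
$ poctbridge --seed 1 analyze
== transcription error report ==
values checked             238
values in error              8
error rate (%)            3.36
  SWAP                       6
  TYPO                       2
  OMIT                       0
errors by analyte:
  Cl                         1
  pCO2_tc                    2
  pH_tc                      2
  pO2_tc                     2
  sO2                        1
== study accounting ==
values per study                 238
minutes per CG4                  4.0
minutes per CHEM8                5.5
capture gain (%)                38.5
person-hours                    50.0
```

Reading it: of the 238 hand-entered values in this simulated study, 8 were
wrong — six because a corrected blood-gas triplet was copied from the
measured column (two swapped cartridges × 3 values), two from single-digit
slips (one of them the classic chloride 95→94).  The accounting block is the
closed-form arithmetic above: a 120-minute entry session costs 4.0 min per
blood-gas and 5.5 min per electrolyte cartridge, automation adds the 38.5 %
of each blood-gas result that was never copied by hand, and a 25-animal
cohort at 2 h/study costs 50 person-hours of typing.

`poctbridge analyze --replicates 20` additionally re-estimates the error
model's configured probabilities from the classified output (parameter
recovery with binomial standard errors); `poctbridge fixtures --outdir fx/`
writes one example XML document per message type.

Configuration can also come from a YAML file (`poctbridge --config app.yaml
listen`): listen host/port, sink kind and credentials (`token` overridable
via `$POCTBRIDGE_TOKEN`), panel definitions, generator settings.  See
`poctbridge.config.AppConfig` for the schema.

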