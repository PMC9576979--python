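# Wire dialect

The conversation between the analyzer (device role) and the logger (data
manager role) is a stream of small XML documents over one TCP connection —
one document per message, UTF-8, delimited by root-element completion (no
length prefixes; inter-document whitespace is tolerated).  The dialect is
structurally faithful to POCT1-A conversations — typed messages, monotone
per-sender control ids, per-message acknowledgment — but uses its own
documented element names.

Conventions:

* The **root element name is the message-type code** (`HEL.R01`, `ACK.R01`,
  `DST.R01`, `OBS.R01`, `EOT.R01`, `END.R01`).
* Every message carries a `HDR` child with `control_id` (positive integer,
  strictly increasing within one sender's session), `version_id` (constant
  `POCT1`) and `creation_time` (ISO-8601, seconds precision, UTC, no
  offset).
* Leaf fields put their value in a `V` attribute.
* Analyte values are decimal **strings** at the device's display precision
  and are persisted byte-identically.
* A single document larger than 1 MiB aborts the session (framing error).

A typical session:

```
device                         manager
  HEL.R01  ──────────────────►
           ◄──────────────────  ACK.R01 (AA)
  DST.R01 (queue depth) ──────►
           ◄──────────────────  ACK.R01 (AA)
  OBS.R01 (one cartridge) ────►
           ◄──────────────────  ACK.R01 (AA after durable write; AE on
                                         persist failure; AR out-of-order)
  ... one OBS.R01 per queued record ...
  EOT.R01  ──────────────────►
  END.R01  ──────────────────►   (both sides close)
```

The device removes a record from its unsent queue **only** after an
`ACK.R01` of type `AA` referencing that observation message's `control_id`.
Anything else — `AE`, `AR`, or silence past the acknowledgment timeout —
retains the record for the next session and raises a "Failed Transmit"
notification on the device UI.

## Annotated examples

All examples below are generated by `poctbridge fixtures` (pretty-printed
here; the wire form is unindented).

### HEL.R01 — Hello

Opens the conversation; identifies the device.

```xml
<HEL.R01>
  <HDR>
    <control_id V="1"/>
    <version_id V="POCT1"/>
    <creation_time V="2026-01-05T08:00:00"/>
  </HDR>
  <DEV>
    <device_serial V="SIM-000001"/>          <!-- required, non-empty -->
    <vendor_name V="Abbott Point of Care (simulated)"/>
    <model_name V="i-STAT Alinity (simulated)"/>
    <TOPICS>
      <topic V="OBSERVATIONS"/>              <!-- topics the device can push -->
    </TOPICS>
  </DEV>
</HEL.R01>
```

### ACK.R01 — Acknowledgment

Sent by either role; references the acknowledged message's `control_id`.
`ack_type` is `AA` (accept), `AE` (error, e.g. the sink write failed) or
`AR` (reject, out-of-order message).

```xml
<ACK.R01>
  <HDR>
    <control_id V="1"/>
    <version_id V="POCT1"/>
    <creation_time V="2026-01-05T08:00:00"/>
  </HDR>
  <ACK>
    <ack_control_id V="1"/>   <!-- the message being acknowledged -->
    <ack_type V="AA"/>
    <!-- optional: <note V="human-readable detail"/> -->
  </ACK>
</ACK.R01>
```

### DST.R01 — Device status

Tells the logger how many unsent records are queued.

```xml
<DST.R01>
  <HDR>
    <control_id V="2"/>
    <version_id V="POCT1"/>
    <creation_time V="2026-01-05T08:00:00"/>
  </HDR>
  <STATUS>
    <condition V="READY"/>            <!-- READY | BUSY | FAULT -->
    <new_observations_qty V="2"/>     <!-- unsent-queue depth -->
  </STATUS>
</DST.R01>
```

### OBS.R01 — Observations (one cartridge run)

One message per cartridge result.  `SVC` carries run identity and cartridge
metadata; one `OBS` child per analyte.  (A CG4 message carries 13 `OBS`
elements; a CHEM8 message, as below, 11.)

```xml
<OBS.R01>
  <HDR>
    <control_id V="3"/>
    <version_id V="POCT1"/>
    <creation_time V="2026-01-05T08:00:00"/>
  </HDR>
  <SVC>
    <result_id V="SIM-000001-20260105081400-0001"/>  <!-- idempotency key -->
    <observation_time V="2026-01-05T08:14:00"/>
    <!-- optional: <operator_id/>, <patient_or_subject_id/> -->
    <CART>
      <cartridge_name V="CHEM8"/>     <!-- selects the analyte table -->
      <lot_number V="LOTCHEM8001"/>
      <expiration_date V="2026-07-04"/>
      <device_serial V="SIM-000001"/>
    </CART>
    <OBS>
      <observation_id V="Na"/>
      <value V="148"/>                <!-- decimal string, display precision -->
      <units V="mmol/L"/>
      <status V="NORMAL"/>            <!-- NORMAL | OUT_OF_RANGE | SUPPRESSED -->
    </OBS>
    <!-- ... one OBS element per remaining panel analyte ... -->
  </SVC>
</OBS.R01>
```

### EOT.R01 — End of topic

The device has no more observations to push.

```xml
<EOT.R01>
  <HDR>
    <control_id V="4"/>
    <version_id V="POCT1"/>
    <creation_time V="2026-01-05T08:00:00"/>
  </HDR>
</EOT.R01>
```

### END.R01 — Terminate

Closes the session; the optional `NOTE` carries a reason.

```xml
<END.R01>
  <HDR>
    <control_id V="5"/>
    <version_id V="POCT1"/>
    <creation_time V="2026-01-05T08:00:00"/>
  </HDR>
  <NOTE V="session complete"/>
</END.R01>
```

## Sink row formats

The file sink appends one JSON object per row: `metadata.jsonl` plus one
analyte file per cartridge table (`cg4.jsonl`, `chem8.jsonl`).  CSV output
uses the same columns with a header line.  The HTTP sink POSTs the same
rows as a form-encoded REDCap-style record import: fields `token`,
`content=record`, `format=json`, `data=<JSON array of row objects>`.

```json
{"table":"metadata","result_id":"SIM-000001-20260105081400-0001",
 "device_serial":"SIM-000001","vendor_name":"Abbott Point of Care (simulated)",
 "cartridge_name":"CHEM8","lot_number":"LOTCHEM8001",
 "expiration_date":"2026-07-04","observation_time":"2026-01-05T08:14:00",
 "received_time":"2026-01-05T08:00:00"}
{"table":"chem8","result_id":"SIM-000001-20260105081400-0001","Na":"148",
 "K":"6.2","Cl":"96","iCa":"1.20","TCO2":"23","Glu":"177","BUN":"36",
 "Crea":"0.7","Hct":"13","Hgb":"14.0","AnGap":"14"}
```
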