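# Known deviations in the published survey tables

The bundled reference tables transcribe the published per-locality summary
statistics of the 2019 Slovak *Leccinum* mercury survey.  Recomputing the
published health-risk table from the published concentration means (with the
default exposure parameters, THQ on the dry-weight basis) reproduces 58 of
the 64 cells within 1 % plus the rounding resolution of the printed numbers.
The remaining six cells are internally inconsistent with the printed means
and are excluded from golden comparisons (`reference.INCONSISTENT_HEALTH_CELLS`):

| Locality | Cell | Printed | From printed mean |
|---|---|---|---|
| Badín | stem %PTWI | 3.90 | 3.09 |
| Kostoľany p/Tribečom | cap %PTWI | 5.40 | 5.01 |
| Králiky | cap %PTWI | 1.40 | 1.03 (survey narrative: 1.04 %) |
| Počúvadlianske Jazero | stem %PTWI | 2.70 | 2.06 |
| Spišské Tomášovce | stem %PTWI | 19.6 | 22.5 |
| Spišské Tomášovce | stem THQ | 3.74 | 4.28 |

The Králiky cap %PTWI disagreement is resolved by the survey's own narrative
(1.04 %), marking the table cell as a likely typo.  The two Spišské
Tomášovce stem cells are mutually consistent with each other but not with
the printed stem mean of 3.50 mg kg⁻¹ DW, suggesting the health table was
computed from an earlier (or unrounded, differently filtered) stem mean near
3.05 mg kg⁻¹ DW.

Further reported inconsistencies not used anywhere in golden tests:

- The soil table prints Liptovská Lúžna's contamination factor as 3.80 while
  the narrative assigns it 0.8 (low class) and the printed mean 0.18 gives
  3.0 — three mutually inconsistent values.  The narrative per-locality
  factors (which yield the published 3/9/2/2 class split) are the reference
  of record here.
- The abstract counts three localities with THQ > 1, the narrative lists
  four (Levočské Lúky, Spišské Tomášovce, Badín, Osturňa for caps), and the
  printed table contains five cap THQ values above 1 (additionally
  Liptovská Lúžna).  The count is therefore not a golden expectation;
  individual cells are.
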