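# Reference screen tables

Hand-curated transcriptions of the published complementation/recovery
screens of NadA and IspG orthologs expressed in *Escherichia coli* knockout
strains (one row per ortholog, 47 heterologous orthologs plus the *E. coli*
host control in each table).

Token normalization applied during transcription:

| printed form | token here   |
|--------------|--------------|
| `+`          | `+`          |
| `−`          | `-`          |
| `+/−`        | `partial`    |
| `N.T.`       | `NT`         |
| `Detection N.T.` | `detection_NT` (in `ms_detected`) |
| `?`          | `?`          |

The printed combined "complemented/recovered/detected" column is omitted:
its `Detection N.T.` states are folded into `ms_detected`, and the rest of
it is derivable from the outcome columns. `fes_system` values are
comma-joined without spaces (`SufBD,IscU`, `SufBD,IscU(NifU)`).
`is_host_control` flags the *E. coli* row; `is_suf_donor` (NadA table only)
flags the *Bacillus subtilis* row whose SUF operon was the coexpressed
recovery pathway.

MD5 checksums:

    fb306e5015f7d434e94ee274f873b1c7  table1_nada.tsv
    e18ef8af95c606d8611d87d4d55ff021  table2_ispg.tsv
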