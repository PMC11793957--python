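# Panel CSV schema

Long format, one row per participant × completed wave.  This is the
schema the generator writes and every loader validates; user-supplied
panels must match it column for column.

| column | type | meaning |
|---|---|---|
| participant_id | int | stable participant identifier |
| wave | int | survey wave, 1-based (missing waves are absent rows) |
| country | str | recruitment country code (`FR`/`UK`) |
| age | float | years, ≥ 25 |
| gender | str | `woman` / `man` |
| income | float | household net monthly income, euros, ≥ 0 |
| costs | float | unavoidable monthly costs (rent/mortgage, water, residence taxes, energy), euros, ≥ 0 |
| subj_item_1 | float | subjective risk of destitution, 0–100 |
| subj_item_2 | float | subjective risk of losing suitable housing, 0–100 |
| subj_item_3 | float | subjective risk of losing suitable employment, 0–100 |
| gamble_choice_1..7 | int | 1 = chose the 50% × €800 gamble over €100·k for sure |
| delay_choice_1..7 | int | 1 = chose €100 now over €(100 + 10·k) in 90 days |
| financial_strain | str | one of `very difficult`, `quite difficult`, `just about getting by`, `doing alright`, `living comfortably` |

Missing battery items may be encoded as empty cells; preprocessing drops
the affected battery (gamble gaps drop the row, delay gaps only void the
discount count).
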