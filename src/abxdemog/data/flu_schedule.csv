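season_start_year,age_group
2015,5–10
2016,5–10
2017,5–10
2019,11–15
2020,50–65
2021,11–15
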