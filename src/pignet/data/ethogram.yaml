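# Agonistic ethogram for continuous observation of newly regrouped pigs.
# Point behaviours are instantaneous (duration 0); state behaviours carry a
# duration in seconds.  "subtle" behaviours are too brief to score reliably
# beyond the acute post-mixing period and are dropped after subtle_cutoff_s.
behaviours:
  - {code: heads_up,      category: display,      kind: state}
  - {code: parallel_walk, category: display,      kind: state}
  - {code: head_knock,    category: non_damaging, kind: point}
  - {code: lunge,         category: non_damaging, kind: point}
  - {code: shove,         category: non_damaging, kind: point, subtle: true}
  - {code: flick,         category: non_damaging, kind: point, subtle: true}
  - {code: push,          category: non_damaging, kind: state}
  - {code: single_bite,   category: single_bite,  kind: point}
  - {code: bully,         category: unilateral,   kind: state}
  - {code: fight,         category: mutual_fight, kind: state}
  - {code: rest,          category: rest,         kind: state}
  - {code: retreat,       category: retreat,      kind: point}
  - {code: mount,         category: mounting,     kind: point}
  - {code: other,         category: other,        kind: state}
# A bite answered by a bite within this window is a reciprocated exchange
# (a fight), not unilateral aggression; the same window is used to attach a
# terminal retreat to a fight bout.
reciprocation_window_s: 3.0
# A fight bout ends when aggressive acts cease for at least this long.
fight_gap_end_s: 60.0
# Subtle behaviours (shove, flick) are not scored after this time post-mixing.
subtle_cutoff_s: 7200.0
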