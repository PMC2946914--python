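# Window policies for exclusion triggers.
#
# chronic: the condition permanently disqualifies later values; a 30-day
#   lookback also removes values shortly before the first code (workup
#   usually precedes coding).
# medication: marrow/immune-suppressing drug exposure; values within 90
#   days after the code/mention date are excluded.
# surgery: major blood loss; values within 90 days after surgery are
#   excluded (post-operative anemia horizon).
#
# These lengths are configurable site policy, not fixed constants.
chronic:
  lookback_days: 30
  duration_days: chronic
medication:
  lookback_days: 0
  duration_days: 90
surgery:
  lookback_days: 0
  duration_days: 90
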