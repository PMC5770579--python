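# Item weights and skip table for the substance-involvement screen.
# Defaults follow ASSIST V3.0 conventions.  All scoring reads from this
# document; edit here (or pass an alternate file) to change the dialect.
#
# Response codes are small integers indexing into `labels`/`weights`.
# Item 1 (lifetime use) is boolean-coded and never contributes to the
# involvement score; items 2..7 do.
version: assist-3.0
items:
  1:
    labels: [never, "yes"]
    weights: [0, 0]
  2:
    labels: [never, once_or_twice, monthly, weekly, daily_or_almost_daily]
    weights: [0, 2, 3, 4, 6]
  3:
    labels: [never, once_or_twice, monthly, weekly, daily_or_almost_daily]
    weights: [0, 3, 4, 5, 6]
  4:
    labels: [never, once_or_twice, monthly, weekly, daily_or_almost_daily]
    weights: [0, 4, 5, 6, 7]
  5:
    labels: [never, once_or_twice, monthly, weekly, daily_or_almost_daily]
    weights: [0, 5, 6, 7, 8]
  6:
    labels: [never, yes_in_past_3_months, yes_but_not_in_past_3_months]
    weights: [0, 6, 3]
  7:
    labels: [never, yes_in_past_3_months, yes_but_not_in_past_3_months]
    weights: [0, 6, 3]
# Items that add into the involvement score (item 1 is screening only).
contributing_items: [2, 3, 4, 5, 6, 7]
# Items never administered for particular substances.
not_administered:
  tobacco: [5]
# Skip table:
#   item 1 = never  -> branch done, nothing else administered
#   item 2 = never  -> only the items below are still administered
recent_never_still_asked: [6, 7]
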