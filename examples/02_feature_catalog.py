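"""Compute the 84-feature vector for one visit and read it as a queue story.

Featurizes a short walk-in log and prints the congestion state seen by one
arriving patient: how many people are in line (LineCount0), how long they
have been waiting in total (SumWaits), and how busy the scanners are
(InProgressSize) — the quantities that turn out to predict the wait.
"""

import queueflow as qf

config = qf.facility_archetype("xray_walkin", n_days=2, seed=5)
log, _ = qf.generate_log(config)

catalog = qf.build_catalog("walkin")
print(f"catalog: {len(catalog)} features, groups {catalog.group_counts()}")

matrix = qf.featurize_log(log, catalog, slot_minutes=config.slot_minutes,
                          n_servers=config.n_servers)
# the arrival that found the longest line of the simulated fortnight
busiest = matrix.loc[matrix["LineCount0"].idxmax()]
state = busiest[["LineCount0", "SumWaits", "InProgressSize",
                 "NumCompletedToday", "MostRecent1", "AvgWaitForDay"]]
print(f"\nqueue state seen by visit {busiest['visit_id']} "
      f"at {busiest['prediction_time']:%H:%M}:")
print(state.to_string())
print(f"\nrealized wait: {busiest['target']:.0f} min")
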