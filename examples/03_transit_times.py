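"""Transit timing and phenotype from the four annotated timepoints.

Entry = neck closure - entry start; dwell = valve opening - neck closure
(negative when the valve opens early); exit = valve closure - opening;
total = entry + dwell + exit.
"""

from spermacal import EventRecord, classify_transit, compute_transit_times

normal = EventRecord(entry_start=10, neck_close=40, valve_open=100,
                     valve_close=160, embryo_exited=True, observation_end=600)
tt = compute_transit_times(normal, dt=1.0)
print(f"entry {tt.entry_time:.0f} s, dwell {tt.dwell_time:.0f} s, "
      f"exit {tt.exit_time:.0f} s, total {tt.total_transit:.0f} s "
      f"-> {classify_transit(normal).value}")

early_valve = EventRecord(entry_start=10, neck_close=40, valve_open=35,
                          valve_close=90, embryo_exited=True, observation_end=600)
tt = compute_transit_times(early_valve)
print(f"early valve opening gives a negative dwell: {tt.dwell_time:.0f} s")

trapped = EventRecord(entry_start=10, neck_close=40, observation_end=600)
print(f"valve never opens -> {classify_transit(trapped).value}")
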