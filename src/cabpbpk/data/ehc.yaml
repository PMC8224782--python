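# Gallbladder emptying / enterohepatic recirculation defaults.
#
# The gallbladder empties exponentially (half-time below) whenever a meal
# event fires; a fixed fraction of stored bile is ejected per event, the rest
# remains.  A fraction of hepatic bile output continuously bypasses the
# gallbladder into the duodenum.  Meals repeat daily; dosing is fasted, so no
# emptying occurs before the first meal.  Exact clock times of "morning, noon,
# evening" are a config default: for a fasted 8 am dose, lunch at 13:00 (5 h),
# dinner at 19:00 (11 h) and the next breakfast at 8 am (24 h) — the 24 h meal
# reproduces the characteristic secondary plasma peak about one day post-dose.
ehc:
  emptying_half_time: 41.44     # min
  continuous_fraction: 0.10     # bile fraction bypassing the gallbladder
  ejection_fraction: 0.45       # stored fraction ejected per meal event
  refill_time: 241.0            # min, refractory period before refilling resumes
  meal_times: [5.0, 11.0, 24.0] # h post-morning-dose, repeated every 24 h
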