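"""Generate one synthetic test-routine session and inspect its structure.

The routine alternates eight 30-second blocks of exercise and rest
(push-ups, resting, jogging, resting, squatting, resting, crunches,
resting) for a 27-year-old subject resting at 70 bpm.
"""

from wearload import default_script, generate_session, write_session

session = generate_session(script=default_script(age=27, hr_rest=70.0), seed=1)
write_session(session, "scratch_session.jsonl")

print(f"records: {len(session)} (one per second)")
print(f"subject: age {session.age}, resting HR {session.hr_rest} bpm")
first, last = session.records[0], session.records[-1]
print(f"first second: label={first.label}, mean HR={first.mean_hr:.1f} bpm, "
      f"{len(first.samples)} accelerometer samples")
print(f"last second:  label={last.label}, mean HR={last.mean_hr:.1f} bpm")
# The first block is push-ups, so HR has climbed from rest toward the
# push-up target by the end of the final resting block it has relaxed back.
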