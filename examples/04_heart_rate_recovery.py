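"""Automated heart-rate-recovery (HRR) detection.

Finds exertion episodes from the intensity series, takes the peak heart
rate and the next interval sample as the recovered rate, and averages
episode HRR into the participant's singular measurement.
"""

import frailscreen as fs
from frailscreen import energy, gait, hrr
from frailscreen.synthetic import (
    generate_accel_stream,
    generate_cohort,
    generate_hr_stream,
)

config = fs.CohortConfig(n_participants=3, duration_days=0.25,
                         accel_rate_hz=25.0, seed=7)
participant, _ = generate_cohort(config)[0]
accel = generate_accel_stream(participant, config)

bouts = gait.segment_bouts(gait.detect_steps(accel))
epochs = energy.classify_epochs(
    energy.epoch_energy(accel), energy.walking_reference(accel, bouts)
)
hr_stream = generate_hr_stream(participant, accel, config)
episodes = hrr.detect_episodes(hr_stream, epochs)
result = hrr.average_hrr(episodes)

print(f"participant {participant.id}: true HRR = {participant.true_hrr_bpm:.1f} bpm")
for e in episodes:
    print(f"  episode at t={e.t_peak_s:6.0f} s: peak {e.hr_max_bpm:.0f}, "
          f"recovered {e.hr_recovered_bpm:.0f}, HRR {e.hrr_bpm:.1f} bpm")
print(f"mean HRR over {result.n_episodes} episodes: {result.mean_hrr_bpm:.1f} bpm "
      f"(screener delta {result.mean_screener_delta_bpm:.1f})")

# The mean HRR estimates the latent recovery capacity; the screener delta
# (its negative) is what the diagnostic validation consumes, so that
# negative cutoffs mean "recovery smaller than X bpm screens positive".
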