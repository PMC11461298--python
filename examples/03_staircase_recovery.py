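"""Locate a clip's category-recognition frame with the up-down staircase.

A 300-frame clip is 'watched' by simulated observers whose recognition
switches on at frame r = 80: below r they guess (1 in 3 correct for a
three-category task), at or above r they answer correctly.  One staircase
iteration is one participant; correct answers shorten the next played
segment, errors lengthen it, with steps N(n) = Nframe/2 * 2^(-(n-2)/2.5)
until N < 1 frame.
"""

from stimchar import ObserverModel, convergence_iteration, run_staircase, step_size

N_FRAME, R_TRUE = 300, 80

deterministic = run_staircase(N_FRAME, lambda played: played >= R_TRUE)
observer = ObserverModel(r=R_TRUE, guess_rate=1 / 3, lapse_rate=0.05, seed=1)
stochastic = run_staircase(N_FRAME, observer)

print(f"schedule: {convergence_iteration(N_FRAME)} iterations "
      f"(first step {step_size(N_FRAME, 2):.0f}, last >1-frame step at n=20)")
print(f"deterministic observer: converged on frame {deterministic.convergence_frame} "
      f"(true r = {R_TRUE})")
print(f"stochastic observer:    converged on frame {stochastic.convergence_frame}")
# The deterministic run lands within one frame of r; guessing observers add
# noise of a few frames (occasionally tens) in any single run.
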