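"""Play 20 adaptive training sessions and watch difficulty track ability.

Each session runs six 3-minute exercises in random order; staircases and
level rules carry difficulty across sessions, so a stronger child ends the
program at harder settings.
"""

from eftrial.policies import make_policy
from eftrial.tasks import SessionState, run_training_session
from eftrial.tasks.training import EXERCISE_DOMAINS

for label, z in (("weaker child (z=-1)", -1.0), ("stronger child (z=+1)", +1.0)):
    policies = {ex: make_policy(dom, z) for ex, dom in EXERCISE_DOMAINS.items()}
    state = SessionState()
    for i in range(20):
        run_training_session(policies, state, seed=100 + i, session_index=i + 1)
    print(label)
    print(f"  final stop-exercise SSD : {state.ssd:.0f} ms "
          "(higher = harder for an anticipated response)")
    print(f"  span lengths (vis/verb) : {state.vspan_length} / {state.dspan_length}")
    print(f"  flanker level           : {state.flanker_level}")
    print(f"  matching ladder rung    : {state.matching_rung} "
          "(0..3 = dimension changes after 12/8/6/4 correct)")
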