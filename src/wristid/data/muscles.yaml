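# Default wrist prime-mover table, cursor convention: extension = +x (right),
# radial deviation = +y (up), angles in degrees counter-clockwise from +x.
#
# preferred_direction: movement direction of maximal activity (surface-EMG
#   cosine fits); used for directional tuning and agonist assignment.
# action_direction: direction of mechanical pull in cursor space; used by the
#   synthetic generator to build torque-consistent tensions.  Note the two can
#   differ substantially (ECU, FCR): activity tuning reflects task dynamics,
#   not just the moment arm.
# sign_x / sign_y: admissible sign of the tension-to-torque weight a_i on each
#   axis (+1, -1, or 0 = unconstrained).
muscles:
  - name: ECR
    preferred_direction: 68.0
    action_direction: 30.0
    sign_x: 1
    sign_y: 1
  - name: ECU
    preferred_direction: 125.0
    action_direction: 315.0
    sign_x: 1
    sign_y: -1
  - name: FCU
    preferred_direction: 189.0
    action_direction: 225.0
    sign_x: -1
    sign_y: -1
  - name: FCR
    preferred_direction: 265.0
    action_direction: 135.0
    sign_x: -1
    sign_y: 1
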