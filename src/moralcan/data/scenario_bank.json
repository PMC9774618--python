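{
  "description": "Scene-framework bank for the 2x2 (egoistic x altruistic) everyday-dilemma battery. Thirteen candidate frameworks entered validation; each has four cell versions. Full scenario text is included for the worked 'stranger' (public smoking) framework; other free-text fields are optional metadata.",
  "validation_sample_size": 209,
  "frameworks": [
    {
      "id": "friend_1",
      "short_name": "a friend asks to board a pet at your home",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "friend_2",
      "short_name": "a sick friend needs your care",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "relative_1",
      "short_name": "a relative asks you to borrow money",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "relative_2",
      "short_name": "a relative asks you to be a tour guide for a trip",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "colleague_1",
      "short_name": "a colleague asks you to do works on their behalf",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "colleague_2",
      "short_name": "a colleague faces an examination",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "neighbor_1",
      "short_name": "a neighbor practices piano out loud",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "neighbor_2",
      "short_name": "a neighbor asks you to collect delivery",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "stranger",
      "short_name": "a stranger is smoking in public",
      "cells": [
        {
          "cell": "EGO_NONALT",
          "text": "You are eating at a restaurant and you see a person smoking at the table. If you leave alone, you can have a fresh dining environment without any conflict with the smoker, but other diners will continue to inhale secondhand smoke.",
          "proposed_behavior": "leave the restaurant alone"
        },
        {
          "cell": "EGO_ALT",
          "text": "You are eating at a restaurant and you see a person smoking at the table. Others in the restaurant did not try to stop him/her. If you stop the smoker, he/she will extinguish the cigarette as a sign of apology, and everyone will praise you for your behavior.",
          "proposed_behavior": "stop the smoker"
        },
        {
          "cell": "NONEGO_ALT",
          "text": "You are eating at a restaurant and you see a person smoking at the table. If you walk over to him/her and remind him/her not to smoke in public, he/she is offended by your stopping him/her and may get into a physical confrontation with you at any time, but other diners will get a fresh dining environment.",
          "proposed_behavior": "stop the smoker"
        },
        {
          "cell": "NONEGO_NONALT",
          "text": "You are eating at a restaurant and you see a person smoking at the table. Others in the restaurant did not try to stop him/her. If you choose to remain silent, you and other diners will continue to inhale secondhand smoke and suffer health consequences.",
          "proposed_behavior": "remain silent"
        }
      ]
    },
    {
      "id": "supermarket_staff",
      "short_name": "a supermarket staff neglects their duties",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "salesperson",
      "short_name": "a salesperson asks you to sign up for a membership",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "blogger",
      "short_name": "a blogger made a mistake in the post",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    },
    {
      "id": "online_purchase",
      "short_name": "an online purchase needs your evaluation",
      "cells": [
        {"cell": "EGO_NONALT", "text": null, "proposed_behavior": null},
        {"cell": "EGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_ALT", "text": null, "proposed_behavior": null},
        {"cell": "NONEGO_NONALT", "text": null, "proposed_behavior": null}
      ]
    }
  ]
}
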