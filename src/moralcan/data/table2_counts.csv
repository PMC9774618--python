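framework_id,short_name,cell,n_consistent,n_total
friend_1,a friend asks to board a pet at your home,EGO_NONALT,178,209
friend_1,a friend asks to board a pet at your home,EGO_ALT,124,209
friend_1,a friend asks to board a pet at your home,NONEGO_ALT,131,209
friend_1,a friend asks to board a pet at your home,NONEGO_NONALT,117,209
friend_2,a sick friend needs your care,EGO_NONALT,131,209
friend_2,a sick friend needs your care,EGO_ALT,181,209
friend_2,a sick friend needs your care,NONEGO_ALT,151,209
friend_2,a sick friend needs your care,NONEGO_NONALT,111,209
relative_1,a relative asks you to borrow money,EGO_NONALT,102,209
relative_1,a relative asks you to borrow money,EGO_ALT,168,209
relative_1,a relative asks you to borrow money,NONEGO_ALT,134,209
relative_1,a relative asks you to borrow money,NONEGO_NONALT,145,209
relative_2,a relative asks you to be a tour guide for a trip,EGO_NONALT,116,209
relative_2,a relative asks you to be a tour guide for a trip,EGO_ALT,181,209
relative_2,a relative asks you to be a tour guide for a trip,NONEGO_ALT,158,209
relative_2,a relative asks you to be a tour guide for a trip,NONEGO_NONALT,128,209
colleague_1,a colleague asks you to do works on their behalf,EGO_NONALT,58,209
colleague_1,a colleague asks you to do works on their behalf,EGO_ALT,172,209
colleague_1,a colleague asks you to do works on their behalf,NONEGO_ALT,154,209
colleague_1,a colleague asks you to do works on their behalf,NONEGO_NONALT,120,209
colleague_2,a colleague faces an examination,EGO_NONALT,133,209
colleague_2,a colleague faces an examination,EGO_ALT,160,209
colleague_2,a colleague faces an examination,NONEGO_ALT,130,209
colleague_2,a colleague faces an examination,NONEGO_NONALT,124,209
neighbor_1,a neighbor practices piano out loud,EGO_NONALT,119,209
neighbor_1,a neighbor practices piano out loud,EGO_ALT,184,209
neighbor_1,a neighbor practices piano out loud,NONEGO_ALT,152,209
neighbor_1,a neighbor practices piano out loud,NONEGO_NONALT,64,209
neighbor_2,a neighbor asks you to collect delivery,EGO_NONALT,146,209
neighbor_2,a neighbor asks you to collect delivery,EGO_ALT,162,209
neighbor_2,a neighbor asks you to collect delivery,NONEGO_ALT,143,209
neighbor_2,a neighbor asks you to collect delivery,NONEGO_NONALT,104,209
stranger,a stranger is smoking in public,EGO_NONALT,118,209
stranger,a stranger is smoking in public,EGO_ALT,175,209
stranger,a stranger is smoking in public,NONEGO_ALT,139,209
stranger,a stranger is smoking in public,NONEGO_NONALT,126,209
supermarket_staff,a supermarket staff neglects their duties,EGO_NONALT,104,209
supermarket_staff,a supermarket staff neglects their duties,EGO_ALT,182,209
supermarket_staff,a supermarket staff neglects their duties,NONEGO_ALT,95,209
supermarket_staff,a supermarket staff neglects their duties,NONEGO_NONALT,128,209
salesperson,a salesperson asks you to sign up for a membership,EGO_NONALT,145,209
salesperson,a salesperson asks you to sign up for a membership,EGO_ALT,185,209
salesperson,a salesperson asks you to sign up for a membership,NONEGO_ALT,153,209
salesperson,a salesperson asks you to sign up for a membership,NONEGO_NONALT,117,209
blogger,a blogger made a mistake in the post,EGO_NONALT,125,209
blogger,a blogger made a mistake in the post,EGO_ALT,181,209
blogger,a blogger made a mistake in the post,NONEGO_ALT,145,209
blogger,a blogger made a mistake in the post,NONEGO_NONALT,133,209
online_purchase,an online purchase needs your evaluation,EGO_NONALT,94,209
online_purchase,an online purchase needs your evaluation,EGO_ALT,166,209
online_purchase,an online purchase needs your evaluation,NONEGO_ALT,102,209
online_purchase,an online purchase needs your evaluation,NONEGO_NONALT,62,209
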