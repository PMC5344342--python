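# 40 future life events used in a standard comparative-optimism rating study.
# base_rate = group mean perceived frequency ("out of 100") / 100.
# desirability (-5..+5) and controllability (0..10) are SYNTHETIC hand-assigned
# plausible event-level means (the source study reports these only qualitatively).
label,base_rate,desirability,controllability
Own own home,0.7235,4.2,6.5
Like job after university,0.5278,4.0,5.5
Starting salary >20k,0.5316,3.0,5.0
Not spend a night in hospital in 5 years,0.5338,2.5,3.0
Have a mentally gifted child,0.1962,2.8,1.0
Visit Amazonian rainforest,0.1031,2.2,8.0
Home's value doubles in 5 years,0.2550,2.6,1.5
Live past 90 years old,0.2258,3.2,3.5
Maintain a constant weight for 10 years,0.3286,2.0,7.0
Graduate with a first,0.2571,3.8,8.5
Work recognised with an award,0.1139,3.4,4.5
Last whole winter without being ill,0.2891,2.4,3.0
Receive good job offer before graduating,0.2705,3.9,6.0
Starting salary >30k,0.2620,3.3,4.5
Achievements acknowledged in national press,0.0753,2.9,3.0
Earn >80k in 10 years time,0.1624,3.1,4.0
Nationwide recognition within profession,0.0711,3.0,4.0
Starting salary >40k,0.1328,3.5,4.0
Marry a millionaire,0.0401,0.8,2.0
Marry a film star,0.0110,-0.8,1.5
Contract AIDS,0.0333,-5.0,7.5
Divorced within 5 years of marriage,0.3256,-3.8,6.0
Lung cancer,0.1257,-4.8,6.5
Have a drinking problem,0.1335,-4.0,7.5
Be sued,0.1051,-3.2,4.0
Be fired from a job,0.2228,-3.5,5.5
Heart attack before 40,0.0609,-4.6,5.0
Be unable to have children,0.1120,-3.9,1.5
Heart attack,0.1748,-4.4,5.0
Have car stolen,0.2019,-2.8,3.0
Out of work for 6 months,0.3727,-3.4,4.5
Be the victim of a mugging,0.2425,-3.6,2.5
Buy a car that turns out to be terrible,0.3935,-2.2,6.0
Realise chose the wrong career,0.3466,-3.0,6.5
Be the victim of burglary,0.4074,-3.1,3.5
Be in bed ill for 2 or more days in a year,0.6706,-1.8,3.5
Forced to take an unattractive job,0.4978,-2.6,5.0
Cancer,0.3231,-4.9,3.5
Break a bone,0.4839,-2.4,3.0
Injured in a road accident,0.2692,-3.7,3.0
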