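payer,code_key,fee_usd
commercial,bp_monitor_education,60.61326093606608
commercial,bp_setup_education,3.5390027531355153
commercial,cbc_auto_diff,7.73114728520907
commercial,depression_screen,6.276414309484193
commercial,hba1c_test,19.322888495943417
commercial,lipid_panel,26.64710401891253
commercial,office_visit,147.4187122945704
commercial,tobacco_cessation,10.38936170212766
medicaid,bp_setup_education,2.056835637480799
medicaid,cbc_auto_diff,3.5949582027168234
medicaid,depression_screen,3.9660751565762005
medicaid,hba1c_test,8.989942528735632
medicaid,lipid_panel,12.40231591448931
medicaid,office_visit,66.1400208986416
medicaid,tobacco_cessation,4.716152019002375
medicare,bp_monitor_education,42.38241839762611
medicare,bp_setup_education,2.474530168150346
medicare,cbc_auto_diff,3.884964682139253
medicare,depression_screen,4.391318977119784
medicare,hba1c_test,9.709973091153717
medicare,lipid_panel,13.39124617737003
medicare,office_visit,103.08997645475951
medicare,tobacco_cessation,7.265672782874618
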