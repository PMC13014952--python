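state,effective_date,covariate_complete
Alabama,,1
Alaska,,1
Arizona,,1
Arkansas,,1
California,2016-01-01,1
Colorado,2019-01-01,1
Connecticut,1999-10-01,0
Delaware,2018-12-27,1
Florida,2018-03-09,1
Georgia,,1
Hawaii,2020-01-01,1
Idaho,,0
Illinois,2019-01-01,1
Indiana,2005-07-01,1
Iowa,,1
Kansas,,1
Kentucky,,1
Louisiana,,1
Maine,,0
Maryland,2018-10-01,1
Massachusetts,2018-08-17,1
Michigan,,1
Minnesota,,1
Mississippi,,1
Missouri,,1
Montana,,1
Nebraska,,1
Nevada,2020-01-01,1
New Hampshire,,0
New Jersey,2019-09-01,1
New Mexico,2020-05-20,1
New York,2019-08-24,1
North Carolina,,1
North Dakota,,0
Ohio,,1
Oklahoma,,1
Oregon,2018-01-01,1
Pennsylvania,,1
Rhode Island,2018-06-01,1
South Carolina,,1
South Dakota,,0
Tennessee,,1
Texas,,0
Utah,,1
Vermont,2018-04-11,1
Virginia,2020-07-01,1
Washington,2016-12-08,1
West Virginia,,1
Wisconsin,,1
Wyoming,,0
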